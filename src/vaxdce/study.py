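"""Default study configuration: herpes zoster vaccination in urban China.

The package is generic over :class:`~vaxdce.design.StudyDesignSpec`, but it
ships the configuration of the motivating application — a discrete choice
experiment on herpes zoster (HZ) vaccination preferences among Chinese
urban residents aged 25+.  Seven attributes describe a hypothetical HZ
vaccine: effectiveness (protection rate), protection duration, number of
doses, risk of influenza-like symptoms, risk of skin reactions, place of
origin, and out-of-pocket price.  Respondents answer 8 choice tasks (two
designed vaccines plus a "no vaccination" opt-out) drawn from one of 4
questionnaire versions blocked out of a 32-task orthogonal design.

``hz_true_parameters`` provides the published mean preference weights for
this setting, used as the default truth of the synthetic-respondent
generator.  The per-yuan price coefficient is −0.00282: the value implied
by the published willingness-to-pay ratios (the display-rounded per-yuan
figure of −0.003 is too coarse to reproduce them).
"""

from __future__ import annotations

import numpy as np

from .design import CATEGORICAL, CONTINUOUS, AttributeSpec, StudyDesignSpec

#: Mean preference weights (utility units; price in utility per CN¥).
HZ_MEAN_COEFFICIENTS: dict[str, float] = {
    "const": 2.804,
    "effectiveness_60": 0.958,
    "effectiveness_75": 1.751,
    "effectiveness_90": 2.746,
    "duration_5": 0.404,
    "duration_10": 0.678,
    "duration_20": 1.013,
    "doses_2": -0.001,
    "flu_risk_5_100": -0.162,
    "flu_risk_10_100": -0.166,
    "flu_risk_20_100": -0.272,
    "skin_risk_5_100": -0.154,
    "skin_risk_10_100": -0.233,
    "skin_risk_20_100": -0.291,
    "origin_imported": -0.354,
    "price": -0.00282,
}

#: Sociodemographic category proportions of the surveyed population
#: (n = 2864 urban residents from 9 cities).
HZ_DEMOGRAPHIC_PROPORTIONS: dict[str, dict[str, float]] = {
    "region": {"eastern": 1523 / 2864, "central": 641 / 2864, "western": 700 / 2864},
    "sex": {"female": 1746 / 2864, "male": 1118 / 2864},
    "age_group": {"25-39": 1114 / 2864, "40-59": 929 / 2864, ">=60": 821 / 2864},
    "marital_status": {
        "unmarried": 252 / 2864, "married": 2463 / 2864, "divorced_or_widowed": 149 / 2864,
    },
    "education": {
        "primary_or_below": 537 / 2864, "middle_school": 588 / 2864,
        "high_school": 581 / 2864, "junior_college": 452 / 2864,
        "bachelor_or_higher": 706 / 2864,
    },
    "occupation": {
        "manual_laborer": 1053 / 2864, "retiree": 613 / 2864,
        "unemployed": 463 / 2864, "white_collar": 735 / 2864,
    },
    "income": {
        "<=40k": 741 / 2864, "40k-80k": 641 / 2864,
        "80k-120k": 644 / 2864, ">120k": 838 / 2864,
    },
}

#: Study sample size (respondents).
HZ_N_RESPONDENTS = 2864


def hz_attributes() -> tuple[AttributeSpec, ...]:
    """The seven HZ vaccine attributes with their levels and coding."""
    return (
        AttributeSpec("effectiveness", ("45", "60", "75", "90"),
                      CATEGORICAL, reference_level="45"),
        AttributeSpec("duration", ("2", "5", "10", "20"),
                      CATEGORICAL, reference_level="2"),
        AttributeSpec("doses", ("1", "2"), CATEGORICAL, reference_level="1"),
        AttributeSpec("flu_risk", ("1/100", "5/100", "10/100", "20/100"),
                      CATEGORICAL, reference_level="1/100"),
        AttributeSpec("skin_risk", ("1/100", "5/100", "10/100", "20/100"),
                      CATEGORICAL, reference_level="1/100"),
        AttributeSpec("origin", ("domestic", "imported"),
                      CATEGORICAL, reference_level="domestic"),
        AttributeSpec("price", ("0", "400", "800", "1200"),
                      CONTINUOUS, numeric_values=(0.0, 400.0, 800.0, 1200.0)),
    )


def hz_study_spec() -> StudyDesignSpec:
    """HZ study design: 32 tasks in 4 blocks, 2 designed vaccines + opt-out."""
    return StudyDesignSpec(
        attributes=hz_attributes(),
        n_alternatives_per_task=2,
        include_optout=True,
        n_tasks=32,
        n_blocks=4,
    )


def hz_true_parameters(heterogeneity: float = 0.5, price_sd: float = 0.0):
    """Default simulation truth for the HZ study.

    Means are the published preference weights; the standard deviation of
    each random coefficient defaults to ``heterogeneity`` × |mean| (the
    spread of individual preferences was not reported, so a relative
    convention is used), and the price coefficient is non-random by
    default so true willingness to pay is a well-defined ratio.
    """
    from .simulate import TrueParameters  # local import avoids a cycle

    spec = hz_study_spec()
    names = spec.coefficient_columns()
    means = np.array([HZ_MEAN_COEFFICIENTS[n] for n in names])
    sds = heterogeneity * np.abs(means)
    sds[names.index("price")] = price_sd
    return TrueParameters(tuple(names), means, sds)
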