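"""Build the orthogonal choice design for the herpes zoster vaccine study.

Seven attributes (five with 4 levels, two with 2 levels) span 4096
possible vaccine profiles.  A strength-2 orthogonal array samples 32 of
them as choice questions, paired with a second alternative by a cyclic
level shift, and blocked into 4 questionnaire versions of 8 tasks each.
"""

from vaxdce import (
    block_design,
    build_choice_design,
    design_diagnostics,
    enumerate_full_factorial,
    hz_study_spec,
    johnson_orme_min_n,
)

spec = hz_study_spec()
print(f"full factorial: {len(enumerate_full_factorial(spec))} vaccine profiles")

design = build_choice_design(spec, run_size="auto", seed=12345)
design = block_design(design, n_blocks=4, seed=12345, spec=spec)
print(f"orthogonal design: {design.n_tasks} choice questions, "
      f"blocks of {[len(design.tasks_in_block(b)) for b in design.block_ids]}")

diag = design_diagnostics(design, spec)
print(f"max |correlation| between attributes: {diag.max_abs_correlation:.2e} "
      f"(balanced={diag.balanced})")

# Rule-of-thumb sample size: c=4 levels, t=8 tasks, a=3 options per task.
print(f"Johnson-Orme minimum respondents per stratum: "
      f"{johnson_orme_min_n(c=4, t=8, a=3)}")

print("\nfirst choice task (vaccine 1 vs vaccine 2 vs opting out):")
task = design.tasks[0]
for i, profile in enumerate(task.profiles, 1):
    print(f"  vaccine {i}: {profile.as_dict()}")
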