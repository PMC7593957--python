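"""Fit the two-step PLS-DA cascade and screen oils with a reject option.

Model 1 separates EVOO from non-EVOO, model 2 LOO from VOO; each model's
ROC-derived uncertainty range defers boundary oils to the sensory panel
instead of forcing a grade.
"""

from collections import Counter

from olivescreen import (
    ScreeningConfig,
    align_batched,
    fit_screening_model,
    screen,
    simulate_dataset,
)

matrix, truths = simulate_dataset(36, 30, 24, n_batches=2, seed=42)
aligned, _ = align_batched(matrix, n_intervals=50)
cats = [t.category for t in truths]

model = fit_screening_model(aligned, cats, ScreeningConfig(n_permutations=5,
                                                           seed=7))
r1, r2 = model.range1, model.range2
print(f"model 1 (EVOO vs non-EVOO): {model.model1.n_lv} LVs, "
      f"Q2 = {model.diagnostics1.cv.q2[model.model1.n_lv - 1]:.2f}")
if r1.empty:
    print(f"  perfect CV separation: single threshold {r1.single_threshold:.3f}")
else:
    print(f"  uncertainty range: PV in [{r1.lower:.3f}, {r1.upper:.3f}] "
          "-> deferred to the panel")
if r2.empty:
    print(f"model 2 (LOO vs VOO): perfect CV separation, single threshold "
          f"{r2.single_threshold:.3f}")
else:
    print(f"model 2 (LOO vs VOO): uncertainty range [{r2.lower:.3f}, {r2.upper:.3f}]")

decisions = screen(model, aligned)
counts = Counter(d.outcome for d in decisions)
correct = sum(d.outcome == t.category for d, t in zip(decisions, truths))
assigned = sum(d.outcome != "UNCERTAIN" for d in decisions)
print(f"outcomes: {dict(counts)}")
print(f"correct among assigned: {correct}/{assigned} "
      f"({100 * correct / assigned:.1f}%)")
# uncertain oils are not errors: they are exactly the ones a screening tool
# should hand to the sensory panel
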