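"""Segment a phantom end to end and score it against its own gold standard.

Runs all four stages (fused enhancement, proportional threshold,
elongating filters, region post-processing) with the default parameter
profile (α=0.33, ρ=0.081, η=2.23) and prints the FOV-restricted criteria.
"""

from retveins import PhantomSpec, confusion, criteria, generate, segment

phantom = generate(PhantomSpec(seed=1))
mask = segment(phantom.image)

c = confusion(mask, phantom.gold, phantom.fov)
r = criteria(c)
dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
print(f"confusion (FOV only): TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
print(f"Sen {r.sen:.4f}  Spe {r.spe:.4f}  PPV {r.ppv:.4f}  NPV {r.npv:.4f}")
print(f"ACC {r.acc:.4f}  Kappa {r.kappa:.4f}  Dice {dice:.4f}")
# ACC is the fraction of FOV pixels labeled correctly; Kappa corrects that
# agreement for chance given how rare vessel pixels are.
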