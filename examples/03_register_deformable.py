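"""Compensate a smooth synthetic brain-shift field with the full engine.

Warps a phantom by a smooth field (max 4 mm), runs the complete
registration (translation -> rigid -> three-level elastic) and prints the
three-column landmark summary: initial error, after the parametric stage,
after the nonparametric stage.
"""

from usreg import (
    PhantomSpec,
    TransformChain,
    deform_phantom,
    generate_phantom,
    random_smooth_field,
    register,
    tre,
)

case = generate_phantom(PhantomSpec(shape=(64, 64, 64), seed=7))
field = random_smooth_field(case.volume, max_mm=4.0, seed=14)
moved = deform_phantom(case, field)

result = register(moved.mask, case.mask)
par_chain = TransformChain(result.chain.steps[:1])

init = tre(moved.landmarks, case.landmarks)
par = tre(moved.landmarks, case.landmarks, par_chain)
non = tre(moved.landmarks, case.landmarks, result.chain)

print(f"{'stage':<16}{'mTRE (mm)':>10}{'min':>8}{'max':>8}")
for name, rep in [("initial", init), ("parametric", par), ("nonparametric", non)]:
    print(f"{name:<16}{rep.mean:>10.2f}{rep.min:>8.2f}{rep.max:>8.2f}")
print(f"converged: {result.converged}  ({result.stop_reasons})")
# A rigid map cannot express the warp, so the parametric row improves only
# partially; the elastic stage removes most of the remaining error, the
# same ordering the three-column tables of intraoperative studies show.
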