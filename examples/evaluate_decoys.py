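"""Interface quality metrics on a ladder of increasingly wrong models.

Takes a synthetic native complex and slides its TCR away from the groove
in rigid steps, printing Fnat, LRMS, iRMS and DockQ at each step.  LRMS
tracks the displacement exactly, Fnat decays as native contacts are
lost, and the DockQ class walks from High down to Incorrect.
"""

from tcrpmhc import make_toy_complex, make_decoy_ladder
from tcrpmhc.metrics import dockq_report

native = make_toy_complex(seed=8)
displacements = [0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0]

print(f"{'shift':>6} {'Fnat':>6} {'LRMS':>7} {'iRMS':>7} {'DockQ':>6}  class")
for decoy, shift in zip(
    make_decoy_ladder(native, displacements), displacements
):
    r = dockq_report(decoy, native)
    print(
        f"{shift:6.1f} {r.fnat:6.2f} {r.lrms:7.2f} {r.irms:7.2f} "
        f"{r.dockq:6.3f}  {r.quality}"
    )
print(
    "\nshift = rigid TCR translation in Å.  DockQ >= 0.80 is High,\n"
    ">= 0.49 Medium, >= 0.23 Acceptable, below that Incorrect."
)
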