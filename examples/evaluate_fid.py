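"""Evaluate generators with FID, its real-real lower bound, and the FID ratio.

FIDrr — the FID between two disjoint halves of the real set — estimates
the intrinsic variation of the real data and lower-bounds any
real-synthetic FIDrs. The ratio rFID = 1 - (FIDrs - FIDrr)/FIDrs is near 1
when the synthetic set is about as far from the real data as the real
data is from itself, and near 0 when the model explains little of it.

Here the 'real' set is drawn from the fixture blob distribution; the
matched generator samples the same distribution, the shifted one adds a
+64 intensity offset.
"""

import tempfile
import warnings
from pathlib import Path

from synthzoo import Generators
from synthzoo.evaluation import report_table
from synthzoo.fixtures import build_fixture_zoo, synth_image_set

workdir = Path(tempfile.mkdtemp(prefix="synthzoo_example_"))
registry_path, _ = build_fixture_zoo(workdir / "zoo", seed=0)
generators = Generators(registry_source=registry_path, cache_dir=workdir / "cache")

real = synth_image_set(200, seed=3)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the matched model can hit the rFID clamp
    reports = [
        generators.evaluate(mid, real, n_syn=200, seed=5)
        for mid in ("00001_BLOB_MASS", "00005_BLOB_MASS_SHIFT")
    ]

for r in reports:
    print(f"{r.model_id}: FIDrr={r.fid_rr:.1f}  FIDrs={r.fid_rs:.1f}  "
          f"rFID={r.rfid:.3f}  (extractor={r.extractor_id}, seed={r.seed})")

table = report_table(reports)
table.write(workdir / "fid_report.csv")
print(f"\nCSV report written to {workdir / 'fid_report.csv'}")
print("the matched generator's rFID is higher: its distance from the real set "
      "is mostly the real data's own sampling variation, while the shifted "
      "generator's rFID near 0 flags a genuine distribution mismatch.")
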