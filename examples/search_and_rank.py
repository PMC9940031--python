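"""Search the bundled catalog of published models and rank the hits by FID.

The catalog ships with the package and records, for 21 published medical
image generators, their metadata and reported FID scores. Lower FID means
the synthetic distribution sits closer to the real one.
"""

from synthzoo import Generators

generators = Generators()  # defaults to the bundled catalog

hits = generators.find_model(["mammography", "mass"], operator="AND")
print(f"{len(hits)} model(s) match 'mammography' AND 'mass':")
for match in hits:
    print(f"  {match.model_id}  (matched: {', '.join(sorted(match.matched_values))})")

ranked = generators.find_and_rank(
    ["mammography", "mass"], operator="AND", metric="FID", order="asc"
)
print("\nranked by FID (ascending — best first):")
for row in ranked:
    value = "no FID reported" if row.value is None else f"FID {row.value:.2f}"
    print(f"  {row.model_id}: {value}")

best = ranked[0]
print(f"\nbest-ranked model: {best.model_id} at FID {best.value:.2f} — the one "
      "a search-then-generate pipeline would execute.")
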