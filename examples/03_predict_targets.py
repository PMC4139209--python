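"""Seed-site scanning and thermodynamic scoring of a 3'UTR.

Takes the two mature miRNA sequences recovered from the packaged cloning
oligos, scans a toy UTR for reverse-complement seed matches, scores each site
with the simplified stacking table (null accessibility backend) and
aggregates per-gene scores with the log-sum-exp reduction: one site reduces
to its own ddG, extra sites always strengthen the total.
"""

from atromir import (MatureMiRNA, aggregate_score, extract_seed, load_fixture,
                     scan_sites, score_site)

matures = load_fixture("table2_sequences")
for name, seq in matures.items():
    print(f"{name}: mature {seq}  seed (nt 2-8) {extract_seed(MatureMiRNA(name, seq))}")

mir206 = MatureMiRNA("miR-206", matures["miR-206"])
utr = "AAAACAUUCCAAAGGGACAUUCCUUU"  # two miR-206 seed-complement sites
sites = [score_site(s, utr, mir206) for s in scan_sites(utr, mir206)]
print(f"\nUTR {utr}")
for s in sites:
    print(f"  site [{s.start},{s.end})  dG_duplex={s.dG_duplex:+.1f}  "
          f"dG_open={s.dG_open:+.1f}  ddG={s.ddG:+.1f}")
total = aggregate_score([s.ddG for s in sites])
print(f"aggregate ddG_total = {total:.3f} "
      "(more negative than either site: multi-site repression is stronger)")
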