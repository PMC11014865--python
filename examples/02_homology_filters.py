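"""The gates between similarity search output and tree building.

Shows hit-table filtering (e-value threshold 1e-10 inclusive, best hit per
reference dataset, best five per fucoxanthin dinoflagellate library),
homolog-set categorization, the decontamination rule, and the alignment
acceptance filter (drop rows >75% gaps, then require >=100 columns and
>=10 sequences).
"""

from plastosort import categorize_homolog_set, decontaminate, filter_alignment, filter_hits
from plastosort.homology import HitRecord
from plastosort.fixtures import simulate_alignment
from plastosort.taxa import default_scheme

scheme = default_scheme()
query = "Karenia_brevis_9001"

hits = [
    HitRecord(query, "Emiliania_huxleyi_0010", 1e-30, 250.0),
    HitRecord(query, "Emiliania_huxleyi_0022", 1e-20, 180.0),  # 2nd best: dropped
    HitRecord(query, "Prymnesium_parvum_0004", 1e-9, 90.0),    # above threshold
    *(
        HitRecord(query, f"Karlodinium_micrum_{i:04d}", 10.0 ** -(40 - i), 300.0)
        for i in range(7)                                      # 7 paralogs: keep 5
    ),
]
kept = filter_hits(hits, scheme)
print(f"retained {len(kept)} of {len(hits)} hits:")
for h in kept:
    print(f"  {h.subject:<28} dataset={h.subject_dataset:<22} e={h.e_value:.0e}")
print("category:", categorize_homolog_set(query, kept, scheme))

best = HitRecord(query, "Homo_sapiens_0001", 1e-25, 400.0)
print("\nbest hit metazoan at 1e-25 -> keep =", decontaminate(best, scheme))

aln = simulate_alignment(
    n_rows=12, n_cols=120,
    gap_fracs=[0.0] * 10 + [0.80, 0.90],  # two rows over the 75% gap bound
    rng_seed=0,
)
filtered, accepted, report = filter_alignment(aln)
print(
    f"\nalignment: {report['n_rows_in']} rows x {report['n_columns']} cols; "
    f"removed {sorted(report['removed_rows'])} -> "
    f"{'accepted' if accepted else 'rejected'} with {report['n_rows_kept']} rows"
)
print(
    "The e-value bound is inclusive, multiple paralogs are kept only from "
    "fucoxanthin libraries, and a confident bacterial/metazoan best hit "
    "would mark the query as contamination."
)
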