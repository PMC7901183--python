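"""Score pairwise relatedness with the match-ratio statistic (mrs).

mrs = identical genotypes among shared loci / common non-reference loci.
Duplicate samples score near 1, first-degree relatives in between,
unrelated pairs lowest; thresholds are calibrated by simulation.
"""

from cfmix import (
    calibrate_thresholds,
    classical_mds,
    classify,
    generate_panel,
    ibs_distance,
    mrs,
    simulate_pedigree,
)

panel = generate_panel(seed=0)
thr = calibrate_thresholds(panel, n_reps=100, seed=1)
print(f"calibrated thresholds: MZD >= {thr.t_mzd:.3f}, 1st >= {thr.t_first:.3f}")

g = simulate_pedigree(panel, seed=2).genotypes
for a, b, what in [
    ("mother", "mother", "duplicate"),
    ("mother", "bm_donor", "full siblings"),
    ("father", "fetus", "parent-child"),
    ("mother", "father", "unrelated"),
]:
    rec = classify(mrs(g.loc[a].rename(a), g.loc[b].rename(b + "'")), thr)
    print(f"{a:9s} vs {b:9s} ({what:13s}): mrs={rec.mrs:.3f} -> {rec.relationship}")

coords = classical_mds(ibs_distance(g), k=2)
print("\nclassical MDS embedding (dim1, dim2):")
print(coords.round(3))
# related samples land closer together in the embedding
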