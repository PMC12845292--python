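"""Generate one complete synthetic study and write its files.

Produces promoters/miRNAs/transcripts (FASTA), a count matrix with sample
metadata (TSV), a leaf image (PNG), a physiology table (TSV) and the
ground-truth manifest (JSON) under ./sim_out.
"""

from pathlib import Path

from ferromir.datagen import (
    PlantSpec,
    SimConfig,
    gen_count_matrix,
    gen_leaf_image,
    gen_physio_table,
    gen_promoter_set,
)
from ferromir.io import write_fasta, write_manifest

out = Path("sim_out")
out.mkdir(exist_ok=True)

cfg = SimConfig(
    seed=7,
    n_features=500,
    plant_spec=(
        PlantSpec("mir158b", "IDE1", -355),
        PlantSpec("mir396b", "IDE1", -631, sequence="TTCAAGCTT_CTTCTCTC"),
    ),
    n_decoy_promoters=3,
    effect_table={"feat0000": {"FeD_L": 2.0}, "feat0001": {"FeD_L": -2.0}},
)

counts, count_truth = gen_count_matrix(cfg)
counts.to_tsv(out / "counts.tsv", out / "samples.tsv")

promoters, prom_truth = gen_promoter_set(cfg)
write_fasta(promoters, out / "promoters.fasta")
write_manifest(prom_truth, out / "promoter_truth.json")

image, _ = gen_leaf_image(cfg)
image.save_png(out / "leaf.png")

physio, _ = gen_physio_table(cfg)
physio.to_csv(out / "physiology.tsv", sep="\t", index=False)

print(f"count matrix: {counts.counts.shape[0]} features x {counts.counts.shape[1]} samples")
print(f"promoters: {len(promoters)} (2 with planted IDE1, offsets -355 and -631)")
print(f"planted effects: feat0000 log2FC +2 and feat0001 log2FC -2 under Fe deficiency (leaf)")
print(f"files written to {out}/")
# The manifest records every planted parameter, so downstream analyses can
# be scored against known truth.
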