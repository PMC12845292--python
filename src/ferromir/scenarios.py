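"""Canned synthetic study scenarios used for validation and demonstration.

These wire the generators and the analysis stages together into complete,
seeded experiments with known ground truth, so that whole-pipeline
behavior (planted-module recovery, error rates) can be measured with one
call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datagen import (
    DuplexSpec,
    PlantSpec,
    SimConfig,
    gen_count_matrix,
    gen_duplex_set,
    gen_promoter_set,
)
from .diffexp import DESet, call_de
from .integrate import RegulatoryModule, build_modules
from .motifscan import MotifHit, ide1_model, scan_promoters
from .targetpred import TargetHit, predict_targets

__all__ = ["ModuleRecoveryResult", "module_recovery_scenario"]

#: The three true miRNA sequences of the planted-module scenario.
_TRUE_MIRS = {
    "mir01": "TTGGACTGAAGGGAGCTCCCT",
    "mir02": "TGAAGCTGCCAGCATGATCTA",
    "mir03": "TCGGACCAGGCTTCATTCCCC",
}


@dataclass
class ModuleRecoveryResult:
    """Everything the planted-module scenario produced."""

    modules: list[RegulatoryModule]
    planted_pairs: set[tuple[str, str]]
    ide1_hits: list[MotifHit]
    target_hits: list[TargetHit]
    de_mirs: dict[str, DESet]
    target_de: dict[str, DESet]

    @property
    def found_pairs(self) -> set[tuple[str, str]]:
        return {(m.mirna_id, m.target_id) for m in self.modules}

    @property
    def n_false(self) -> int:
        return len(self.found_pairs - self.planted_pairs)

    @property
    def n_recovered(self) -> int:
        return len(self.found_pairs & self.planted_pairs)


def module_recovery_scenario(
    seed: int = 42,
    n_decoy_transcripts: int = 200,
    n_decoy_mirnas: int = 5,
    n_background_mirnas: int = 300,
    dispersion: float = 0.1,
) -> ModuleRecoveryResult:
    """Plant three (IDE1-miRNA, target) modules and run the full pipeline.

    Three miRNAs carry a near-consensus IDE1 in their promoter, a target
    site (penalty 2.0) in their cognate transcript, and strong opposite
    differential expression under Fe deficiency (|log2FC| 2 for both
    partners, NB dispersion ``dispersion``, 3 replicates).  Decoys carry
    partial evidence only: decoy miRNAs lack planted motifs and target
    sites (one is differentially expressed); ten decoy transcripts are
    differentially expressed but have no target site.  Background miRNAs
    keep library sizes dominated by unperturbed features, as in a real
    small-RNA library.
    """
    plant = tuple(
        PlantSpec(m, "IDE1", -300 - 100 * i, substitutions_per_module=(1, 1))
        for i, m in enumerate(sorted(_TRUE_MIRS))
    )
    promoters, _ = gen_promoter_set(
        SimConfig(seed=seed, plant_spec=plant, n_decoy_promoters=n_decoy_mirnas)
    )
    decoy_mirs = sorted(p for p in promoters if p.startswith("decoy"))

    duplexes = tuple(
        DuplexSpec(m, _TRUE_MIRS[m], f"tg{m[-2:]}", edits=((15, "MM"), (18, "MM")))
        for m in sorted(_TRUE_MIRS)
    )
    mirnas, transcripts, _ = gen_duplex_set(SimConfig(seed=seed, duplex_spec=duplexes))
    rng = np.random.default_rng([seed, 99])
    for m in decoy_mirs:
        mirnas[m] = "".join(rng.choice(list("ACGT"), size=21))
    for i in range(n_decoy_transcripts):
        transcripts[f"dec{i:03d}"] = "".join(rng.choice(list("ACGT"), size=300))

    mir_names = tuple(sorted(mirnas)) + tuple(
        f"bgmir{i:03d}" for i in range(n_background_mirnas)
    )
    mir_eff = {
        "mir01": {"FeD_L": 2.0},
        "mir02": {"FeD_L": -2.0},
        "mir03": {"FeD_L": 2.0},
        decoy_mirs[0]: {"FeD_L": 1.5},  # DE decoy without motif or site
    }
    mir_counts, _ = gen_count_matrix(
        SimConfig(
            seed=seed, feature_names=mir_names, dispersion=dispersion, effect_table=mir_eff
        )
    )

    t_names = tuple(sorted(transcripts))
    t_eff: dict[str, dict[str, float]] = {
        "tg01": {"FeD_L": -2.0},
        "tg02": {"FeD_L": 2.0},
        "tg03": {"FeD_L": -2.0},
    }
    for i in range(10):  # DE decoy transcripts without sites, balanced
        t_eff[f"dec{i:03d}"] = {"FeD_L": 2.0 if i % 2 else -2.0}
    t_counts, _ = gen_count_matrix(
        SimConfig(
            seed=seed + 1, feature_names=t_names, dispersion=dispersion, effect_table=t_eff
        )
    )

    ide1_hits = scan_promoters(promoters, [ide1_model()])
    target_hits = predict_targets(mirnas, transcripts, cutoff=2.5)
    de_mirs = {"FeD_L_vs_CK_L": call_de(mir_counts, "FeD_L", "CK_L", assay="miRNA")}
    target_de = {"FeD_L_vs_CK_L": call_de(t_counts, "FeD_L", "CK_L", assay="mRNA")}
    modules = build_modules(ide1_hits, de_mirs, target_hits, target_de)
    return ModuleRecoveryResult(
        modules=modules,
        planted_pairs={("mir01", "tg01"), ("mir02", "tg02"), ("mir03", "tg03")},
        ide1_hits=ide1_hits,
        target_hits=target_hits,
        de_mirs=de_mirs,
        target_de=target_de,
    )
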