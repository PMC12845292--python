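"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the two-organ (leaf L, root R), four-treatment
(Fe-sufficient control CK, 4-d Fe deficiency FeD, 6-h root-resupply RE,
6-h foliar-resupply Fol) factorial design of an Fe-deficiency/recovery
experiment:

* negative-binomial count matrices across the 8 condition groups with
  planted log2 fold-changes,
* promoters carrying IDE1/IDE2 elements at known upstream offsets with a
  controlled number of substitutions per 9-bp module and optional gaps,
* miRNA:transcript pairs whose best duplex has a known penalty score,
* leaf images with a connected region of controlled pixel count and hue,
* physiology tables (metal contents, chlorophyll-fluorescence readings)
  with stated true means and Gaussian noise.

Every planted parameter is recorded in a :class:`GroundTruthManifest` so
downstream stages can be tested for recovery.  All randomness flows from a
single integer seed; each output type draws from its own documented
substream, so generators are independent and individually reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .motifscan import (
    IDE1_CONSENSUS,
    IDE2_CONSENSUS,
    local_to_upstream,
    revcomp,
)

__all__ = [
    "GROUPS",
    "STANDARD_CONTRASTS",
    "SimConfig",
    "PlantSpec",
    "DuplexSpec",
    "ImageSpec",
    "PhysioSpec",
    "GroundTruthManifest",
    "CountData",
    "LeafImage",
    "gen_count_matrix",
    "gen_promoter_set",
    "gen_duplex_set",
    "gen_leaf_image",
    "gen_physio_table",
    "default_physio_specs",
    "default_fluorescence_specs",
]

#: The 8 condition groups: treatment x organ.
GROUPS = (
    "CK_L", "FeD_L", "RE_L", "Fol_L",
    "CK_R", "FeD_R", "RE_R", "Fol_R",
)

#: Contrasts evaluated throughout the pipeline, as (test, reference).
STANDARD_CONTRASTS = tuple(
    (f"{t}_{o}", f"{r}_{o}")
    for o in ("L", "R")
    for t, r in (("FeD", "CK"), ("RE", "CK"), ("Fol", "CK"), ("RE", "FeD"), ("Fol", "FeD"))
)

# Fixed substream identifiers so generators never share a stream.
_STREAMS = {"counts": 1, "promoters": 2, "duplex": 3, "image": 4, "physio": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PlantSpec:
    """One motif planted into one promoter.

    Either an explicit ``sequence`` (e.g. a published variant, with ``_``
    marking a deleted consensus position) or a consensus-derived variant
    with ``substitutions_per_module`` random edits and ``gap_positions``
    deletions (0-based consensus coordinates).
    """

    promoter_id: str
    motif_type: Literal["IDE1", "IDE2"] = "IDE1"
    upstream_offset: int = -355  # 1-based inclusive start, negative
    substitutions_per_module: tuple[int, ...] = (0, 0)
    gap_positions: tuple[int, ...] = ()
    sequence: str | None = None


@dataclass(frozen=True)
class DuplexSpec:
    """One miRNA:transcript pair with edits defining its target site.

    ``edits`` are (1-based miRNA position, op) with op in {"MM", "GU",
    "GAP"}; the site is the reverse complement of the miRNA with those
    edits applied, embedded at ``site_start`` (1-based on the transcript).
    """

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    transcript_length: int = 300
    site_start: int = 100
    edits: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class ImageSpec:
    height: int = 200
    width: int = 200
    foreground_hue: float = 120.0  # HSV degrees
    background_hue: float = 30.0
    foreground_pixels: int = 6000
    foreground_saturation: float = 0.8
    foreground_value: float = 0.8
    background_saturation: float = 0.05
    background_value: float = 0.95


@dataclass(frozen=True)
class PhysioSpec:
    """One measured quantity in one condition with its true mean and noise."""

    tissue: Literal["leaf", "root"]
    treatment: str
    measure: str  # e.g. "Fe", "Mn", "F0", "Fm"
    true_mean: float
    sd: float = 0.0
    timepoint: str = "6h"


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study's default design.

    ``effect_table`` maps feature id -> group label -> true log2 offset of
    that group's mean from ``baseline_mean``; groups absent from a feature's
    entry sit at baseline (log2 offset 0), so the true log2 fold-change of
    contrast (test, ref) is ``offset[test] - offset[ref]``.
    """

    seed: int = 0
    n_features: int = 2000
    groups: tuple[str, ...] = GROUPS
    replicates_per_group: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict)
    feature_prefix: str = "feat"
    feature_names: tuple[str, ...] | None = None  # overrides n_features
    promoter_length: int = 2000
    plant_spec: tuple[PlantSpec, ...] = ()
    n_decoy_promoters: int = 0
    duplex_spec: tuple[DuplexSpec, ...] = ()
    image_spec: ImageSpec = field(default_factory=ImageSpec)
    physio_spec: tuple[PhysioSpec, ...] = ()


@dataclass
class GroundTruthManifest:
    """Machine-readable record of every planted parameter.

    Serializable to JSON and reload-idempotent; sections are filled by the
    generator that owns them.
    """

    schema_version: int = 1
    group_log2_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    true_lfc: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_motifs: list[dict] = field(default_factory=list)
    duplexes: list[dict] = field(default_factory=list)
    image: dict = field(default_factory=dict)
    physio_means: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))

    def contrast_lfc(self, feature: str, test: str, ref: str) -> float:
        off = self.group_log2_offsets.get(feature, {})
        return off.get(test, 0.0) - off.get(ref, 0.0)


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountData:
    """Feature x sample integer counts plus per-sample metadata."""

    counts: pd.DataFrame  # features x samples
    meta: pd.DataFrame  # index: sample; columns: organ, treatment, replicate, group

    def to_tsv(self, counts_path, meta_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample")


def gen_count_matrix(config: SimConfig) -> tuple[CountData, GroundTruthManifest]:
    """Draw NB(mean = baseline * 2^offset, dispersion phi) counts per group.

    The NB is mean/dispersion parameterized (variance = mu + phi * mu^2);
    ``dispersion == 0`` degenerates to Poisson.  The manifest records the
    per-group log2 offsets and the implied true log2 fold-change for every
    standard contrast.
    """
    if config.replicates_per_group < 2:
        raise ValueError("replicates_per_group must be >= 2")
    if config.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    for feat, entry in config.effect_table.items():
        for group, lfc in entry.items():
            if group not in config.groups:
                raise ValueError(f"unknown group label {group!r} for {feat!r}")
            if not math.isfinite(lfc):
                raise ValueError(f"non-finite effect for {feat!r}/{group!r}")

    rng = _rng(config.seed, "counts")
    if config.feature_names is not None:
        features = list(config.feature_names)
    else:
        features = [f"{config.feature_prefix}{i:04d}" for i in range(config.n_features)]
    samples, organ, treatment, repl, group_col = [], [], [], [], []
    for g in config.groups:
        trt, org = g.rsplit("_", 1)
        for r in range(1, config.replicates_per_group + 1):
            samples.append(f"{g}_r{r}")
            organ.append(org)
            treatment.append(trt)
            repl.append(r)
            group_col.append(g)
    meta = pd.DataFrame(
        {"organ": organ, "treatment": treatment, "replicate": repl, "group": group_col},
        index=pd.Index(samples, name="sample"),
    )

    # per-feature, per-group means
    mu = np.full((len(features), len(config.groups)), config.baseline_mean)
    gidx = {g: j for j, g in enumerate(config.groups)}
    fidx = {f: i for i, f in enumerate(features)}
    for feat, entry in config.effect_table.items():
        if feat not in fidx:
            raise ValueError(f"effect_table feature {feat!r} not generated")
        for group, off in entry.items():
            mu[fidx[feat], gidx[group]] = config.baseline_mean * 2.0 ** off

    mats = []
    for j, g in enumerate(config.groups):
        m = np.repeat(mu[:, [j]], config.replicates_per_group, axis=1)
        if config.dispersion == 0:
            draws = rng.poisson(m)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + m)
            draws = rng.negative_binomial(r, p)
        mats.append(draws)
    counts = pd.DataFrame(
        np.hstack(mats), index=pd.Index(features, name="feature"), columns=samples
    )

    manifest = GroundTruthManifest()
    manifest.group_log2_offsets = {
        f: dict(e) for f, e in config.effect_table.items()
    }
    for feat in features:
        entry = {}
        for test, ref in STANDARD_CONTRASTS:
            entry[f"{test}_vs_{ref}"] = manifest.contrast_lfc(feat, test, ref)
        manifest.true_lfc[feat] = entry
    return CountData(counts, meta), manifest


# ---------------------------------------------------------------------------
# promoters


def _consensus_for(motif_type: str) -> str:
    return IDE1_CONSENSUS if motif_type == "IDE1" else IDE2_CONSENSUS


def _build_variant(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Construct the planted sequence and the 0-based edited positions."""
    consensus = _consensus_for(spec.motif_type)
    if spec.sequence is not None:
        return spec.sequence.replace("_", ""), []
    seq = list(consensus)
    edited: list[int] = []
    n_modules = len(consensus) // 9
    subs = spec.substitutions_per_module
    if len(subs) != n_modules:
        raise ValueError(
            f"substitutions_per_module needs {n_modules} entries for {spec.motif_type}"
        )
    for mod, k in enumerate(subs):
        if k > 9:
            raise ValueError("cannot substitute more than 9 positions per module")
        avail = [
            p
            for p in range(mod * 9, mod * 9 + 9)
            if p not in spec.gap_positions
        ]
        pos = rng.choice(len(avail), size=k, replace=False)
        for p in sorted(avail[i] for i in pos):
            alts = [b for b in "ACGT" if b != consensus[p]]
            seq[p] = alts[rng.integers(len(alts))]
            edited.append(p)
    for g in sorted(spec.gap_positions, reverse=True):
        seq[g] = ""
    return "".join(seq), edited


def gen_promoter_set(
    config: SimConfig,
) -> tuple[dict[str, str], GroundTruthManifest]:
    """Uniform-ACGT promoters with the configured motifs planted.

    The planted variant replaces the background at the configured upstream
    offset (1-based inclusive, -1 = base nearest the anchor at the 3' end);
    the manifest records offsets in the same convention the scanner reports.
    Two planted motifs overlapping in one promoter is an error.
    """
    rng = _rng(config.seed, "promoters")
    L = config.promoter_length
    promoters: dict[str, str] = {}
    manifest = GroundTruthManifest()
    by_promoter: dict[str, list[tuple[int, int]]] = {}

    ids = list(dict.fromkeys(s.promoter_id for s in config.plant_spec))
    ids += [f"decoy{i:03d}" for i in range(config.n_decoy_promoters)]
    for pid in ids:
        promoters[pid] = "".join(rng.choice(list("ACGT"), size=L))

    for spec in config.plant_spec:
        variant, edited = _build_variant(spec, rng)
        if not -L <= spec.upstream_offset <= -1:
            raise ValueError(f"offset {spec.upstream_offset} outside promoter")
        start = L + spec.upstream_offset  # 0-based local start
        end = start + len(variant)
        if end > L:
            raise ValueError("planted motif extends past the anchor")
        for s0, e0 in by_promoter.get(spec.promoter_id, []):
            if start < e0 and s0 < end:
                raise ValueError(
                    f"planted motifs overlap in promoter {spec.promoter_id!r}"
                )
        by_promoter.setdefault(spec.promoter_id, []).append((start, end))
        seq = promoters[spec.promoter_id]
        promoters[spec.promoter_id] = seq[:start] + variant + seq[end:]
        us, ue = local_to_upstream(start, end, L)
        manifest.planted_motifs.append(
            {
                "promoter_id": spec.promoter_id,
                "motif_type": spec.motif_type,
                "upstream_start": us,
                "upstream_end": ue,
                "local_start": start,
                "local_end": end,
                "sequence": variant,
                "substitutions_per_module": list(spec.substitutions_per_module)
                if spec.sequence is None
                else None,
                "edited_positions": edited,
                "gap_positions": sorted(spec.gap_positions),
            }
        )
    return promoters, manifest


# ---------------------------------------------------------------------------
# duplexes

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
# penalty constants mirrored from the target-scoring scheme, used only to
# compute the planted duplex's true score for the manifest
_PEN = {"MM": 1.0, "GU": 0.5, "GAP": 2.0}


def _true_score(edits: Sequence[tuple[int, str]], weight_lo=2, weight_hi=13) -> float:
    score = 0.0
    for pos, op in edits:
        w = 2.0 if weight_lo <= pos <= weight_hi else 1.0
        score += w * _PEN[op]
    return score


def gen_duplex_set(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], GroundTruthManifest]:
    """Transcripts embedding miRNA target sites of known penalty score.

    Background transcript sequence is uniform ACGT; the site is the DNA
    reverse complement of the miRNA with the configured edits applied:
    MM rewrites the paired base to one that neither Watson-Crick nor G:U
    pairs with the miRNA base, GU converts a Watson-Crick pair to a G:U
    wobble (only legal opposite G or U), GAP deletes the paired base.
    Returns (mirnas, transcripts, manifest); sequences are DNA-alphabet.
    """
    rng = _rng(config.seed, "duplex")
    mirnas: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    manifest = GroundTruthManifest()
    for spec in config.duplex_spec:
        mir_rna = spec.mirna_seq.upper().replace("T", "U")
        mirnas[spec.mirna_id] = mir_rna.replace("U", "T")
        site = [_RNA_COMP[b] for b in mir_rna]  # site 3'->5' paired to miRNA 5'->3'
        gaps: list[int] = []
        for pos, op in spec.edits:
            i = pos - 1
            m = mir_rna[i]
            if op == "MM":
                # choose a base that neither WC- nor GU-pairs with m
                bad = {_RNA_COMP[m]}
                if m == "G":
                    bad.add("U")
                if m == "U":
                    bad.add("G")
                site[i] = next(b for b in "ACGU" if b not in bad)
            elif op == "GU":
                if m == "G":
                    site[i] = "U"
                elif m == "U":
                    site[i] = "G"
                else:
                    raise ValueError(f"GU edit needs G or U at miRNA pos {pos}")
            elif op == "GAP":
                gaps.append(i)
            else:
                raise ValueError(f"unknown edit op {op!r}")
        for i in sorted(gaps, reverse=True):
            del site[i]
        # site list is 3'->5' on the transcript; transcript text is 5'->3'
        site_dna = "".join(site)[::-1].replace("U", "T")
        tlen = spec.transcript_length
        if not 1 <= spec.site_start <= tlen - len(site_dna) + 1:
            raise ValueError("site does not fit in transcript")
        background = "".join(rng.choice(list("ACGT"), size=tlen))
        s0 = spec.site_start - 1
        transcript = background[:s0] + site_dna + background[s0 + len(site_dna):]
        transcripts[spec.transcript_id] = transcript
        manifest.duplexes.append(
            {
                "mirna_id": spec.mirna_id,
                "transcript_id": spec.transcript_id,
                "site_start": spec.site_start,
                "site_end": spec.site_start + len(site_dna) - 1,
                "edits": [list(e) for e in spec.edits],
                "true_score": _true_score(spec.edits),
            }
        )
    return mirnas, transcripts, manifest


# ---------------------------------------------------------------------------
# images


@dataclass
class LeafImage:
    """8-bit RGB image plus the exact foreground truth mask."""

    rgb: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool
    foreground_hue: float

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.rgb).save(path, format="PNG")


def _hsv_to_rgb8(h_deg: float, s: float, v: float) -> np.ndarray:
    import colorsys

    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return np.array([round(r * 255), round(g * 255), round(b * 255)], dtype=np.uint8)


def gen_leaf_image(config: SimConfig) -> tuple[LeafImage, GroundTruthManifest]:
    """A single connected central region of the configured pixel count/hue.

    The foreground grows as a discrete disk from the image center (pixels
    sorted by squared distance, then row, then column), guaranteeing
    8-connectivity; the background is low-saturation so simple
    saturation/value thresholds separate the two.  Purely deterministic.
    """
    spec = config.image_spec
    H, W = spec.height, spec.width
    if spec.foreground_pixels > H * W:
        raise ValueError("foreground pixel count exceeds image size")
    for hue in (spec.foreground_hue, spec.background_hue):
        if not 0.0 <= hue < 360.0:
            raise ValueError("hue must lie in [0, 360)")
    rr, cc = np.mgrid[0:H, 0:W]
    d2 = (rr - (H - 1) / 2.0) ** 2 + (cc - (W - 1) / 2.0) ** 2
    order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
    mask = np.zeros(H * W, dtype=bool)
    mask[order[: spec.foreground_pixels]] = True
    mask = mask.reshape(H, W)
    rgb = np.empty((H, W, 3), dtype=np.uint8)
    rgb[:] = _hsv_to_rgb8(spec.background_hue, spec.background_saturation, spec.background_value)
    rgb[mask] = _hsv_to_rgb8(spec.foreground_hue, spec.foreground_saturation, spec.foreground_value)
    manifest = GroundTruthManifest()
    manifest.image = {
        "foreground_pixels": int(spec.foreground_pixels),
        "foreground_hue": float(spec.foreground_hue),
        "background_hue": float(spec.background_hue),
        "height": H,
        "width": W,
    }
    return LeafImage(rgb, mask, spec.foreground_hue), manifest


# ---------------------------------------------------------------------------
# physiology


def default_physio_specs(sd: float = 0.0) -> tuple[PhysioSpec, ...]:
    """Metal-content conditions mirroring the study's narrative effects.

    Units are arbitrary (per-mass content); the controls sit at 100 so that
    treated means read directly as percent: root Fe drops 19 % and leaf Fe
    8 % under deficiency, root Cu rises under deficiency, root Mn and Zn
    rise after resupply.
    """
    rows = [
        ("root", "CK", "Fe", 100.0), ("root", "FeD", "Fe", 81.0),
        ("leaf", "CK", "Fe", 100.0), ("leaf", "FeD", "Fe", 92.0),
        ("root", "RE", "Fe", 90.0), ("leaf", "RE", "Fe", 97.0),
        ("root", "CK", "Cu", 100.0), ("root", "FeD", "Cu", 120.0),
        ("leaf", "CK", "Cu", 100.0), ("leaf", "FeD", "Cu", 95.0),
        ("root", "CK", "Mn", 100.0), ("root", "FeD", "Mn", 100.0),
        ("root", "RE", "Mn", 125.0),
        ("leaf", "CK", "Mn", 100.0), ("leaf", "FeD", "Mn", 85.0),
        ("leaf", "RE", "Mn", 100.0),
        ("root", "CK", "Zn", 100.0), ("root", "FeD", "Zn", 100.0),
        ("root", "RE", "Zn", 118.0),
    ]
    return tuple(PhysioSpec(t, trt, m, mean, sd) for t, trt, m, mean in rows)


def default_fluorescence_specs(sd: float = 0.0) -> tuple[PhysioSpec, ...]:
    """Dark/light-adapted fluorescence readings per treatment.

    Control F0/Fm give Fv/Fm = 0.78; deficiency raises F0 to 0.26
    (Fv/Fm = 0.74); both resupply routes recover to 0.76.  Fm'/Fs are set
    so Y(II) falls under deficiency and recovers with resupply.
    """
    rows = [
        ("leaf", "CK", "F0", 0.22), ("leaf", "CK", "Fm", 1.0),
        ("leaf", "CK", "Fmp", 0.80), ("leaf", "CK", "Fs", 0.44),
        ("leaf", "FeD", "F0", 0.26), ("leaf", "FeD", "Fm", 1.0),
        ("leaf", "FeD", "Fmp", 0.80), ("leaf", "FeD", "Fs", 0.56),
        ("leaf", "RE", "F0", 0.24), ("leaf", "RE", "Fm", 1.0),
        ("leaf", "RE", "Fmp", 0.80), ("leaf", "RE", "Fs", 0.48),
        ("leaf", "Fol", "F0", 0.24), ("leaf", "Fol", "Fm", 1.0),
        ("leaf", "Fol", "Fmp", 0.80), ("leaf", "Fol", "Fs", 0.48),
    ]
    return tuple(PhysioSpec(t, trt, m, mean, sd) for t, trt, m, mean in rows)


def gen_physio_table(config: SimConfig) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Replicated measurements with Gaussian noise truncated at zero.

    Columns: tissue, treatment, timepoint, measure, replicate, value.
    """
    if config.replicates_per_group < 2:
        raise ValueError("replicates_per_group must be >= 2")
    specs = config.physio_spec or (default_physio_specs() + default_fluorescence_specs())
    rng = _rng(config.seed, "physio")
    rows = []
    manifest = GroundTruthManifest()
    for spec in specs:
        if spec.true_mean < 0:
            raise ValueError("true mean must be >= 0")
        if spec.sd < 0:
            raise ValueError("noise SD must be >= 0")
        for r in range(1, config.replicates_per_group + 1):
            value = spec.true_mean + (rng.normal(0.0, spec.sd) if spec.sd > 0 else 0.0)
            rows.append(
                {
                    "tissue": spec.tissue,
                    "treatment": spec.treatment,
                    "timepoint": spec.timepoint,
                    "measure": spec.measure,
                    "replicate": r,
                    "value": max(0.0, value),
                }
            )
        manifest.physio_means.append(asdict(spec))
    return pd.DataFrame(rows), manifest
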