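"""Synthetic miRNA/mRNA expression data with planted, recoverable structure.

The generator emulates the design of a multi-condition muscle-atrophy study:
eight conditions (control, denervation at 3/7/14 days, starvation at 24/48 h,
streptozotocin diabetes, C26 cancer cachexia), ~400 miRNA probes and a few
thousand mRNA probes measured as log2(atrophy/control) ratios, with
below-detection dropout.  Three layers of structure are planted:

* focal miRNAs (default: miR-206- and miR-21-like) up-regulated in late
  denervation, each with a set of target genes repressed wherever the miRNA
  is up, some targets shared between the two miRNAs;
* per-condition miRNA signature blocks, so that samples of the same (or
  kinetically related) condition resemble each other and conditions separate
  in a dendrogram, each catabolic state carrying its own signature;
* a transcriptional "atrophy program" among the mRNAs that peaks at 3 days
  of denervation while the miRNA response peaks at 7 days (the kinetic shift
  between transcript and miRNA regulation).

Everything planted is recorded in :class:`GroundTruth` so downstream stages
can be scored for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleMeta

__all__ = ["SimulationConfig", "GroundTruth", "simulate_expression", "simulate_utrs",
           "DEFAULT_CONDITIONS", "DEFAULT_MATURE_SEQS"]

DEFAULT_CONDITIONS = ("control", "Den3", "Den7", "Den14", "STV24", "STV48", "STZ", "C26")

_TIMEPOINTS = {"control": 0.0, "Den3": 3.0, "Den7": 7.0, "Den14": 14.0,
               "STV24": 1.0, "STV48": 2.0, "STZ": 7.0, "C26": 14.0}

# Mature sequences of the two focal miRNAs (identical to the packaged
# cloning-oligo fixture; duplicated here so simulation needs no file access).
DEFAULT_MATURE_SEQS = {
    "miR-206": "UGGAAUGUAAGGAAGUGUGUGG",
    "miR-21": "UAGCUUAUCAGACUGAUGUUGA",
}

RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _default_planted() -> dict[str, dict[str, float]]:
    # Both focal miRNAs induced in late denervation; response peaks at day 7.
    return {
        "miR-206": {"Den7": 1.5, "Den14": 1.0},
        "miR-21": {"Den7": 1.5, "Den14": 1.0},
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``planted_mirnas`` maps miRNA name -> {condition: log2 fold change}; these
    are the target-bearing miRNAs.  ``signature_mirnas_per_block`` controls the
    per-condition signature blocks that make conditions separable in a
    dendrogram (0 disables them).  ``dropout_threshold`` is a log2-intensity
    detection limit applied to simulated per-spot abundance.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_mirna: int = 400
    n_mrna: int = 2000
    replicates: int = 3
    noise_sd: float = 0.25
    dropout_threshold: float = 5.0
    abundance_mean: float = 8.0
    abundance_sd: float = 1.5
    intensity_noise_sd: float = 1.0
    planted_mirnas: dict[str, dict[str, float]] = field(default_factory=_default_planted)
    targets_per_mirna: int = 30
    shared_targets: int = 10
    repression_log2fc: float = -1.0
    sites_per_target_max: int = 3
    kinetic_shift: bool = True
    n_program_mrna: int = 200
    program_log2fc: float = 1.0
    signature_mirnas_per_block: int = 25
    signature_log2fc: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.repression_log2fc >= 0:
            raise ValueError("repression_log2fc must be negative")
        if self.shared_targets > self.targets_per_mirna:
            raise ValueError("shared_targets cannot exceed targets_per_mirna")
        for n in (self.n_mirna, self.n_mrna, self.replicates):
            if n <= 0:
                raise ValueError("counts must be positive")
        n_unique = len(self.planted_mirnas) * (self.targets_per_mirna - self.shared_targets)
        n_target_genes = n_unique + (self.shared_targets if self.planted_mirnas else 0)
        if n_target_genes + self.n_program_mrna > self.n_mrna:
            raise ValueError(
                f"cannot plant {n_target_genes} targets + {self.n_program_mrna} "
                f"program genes among {self.n_mrna} mRNAs"
            )
        unknown = {c for eff in self.planted_mirnas.values() for c in eff} - set(self.conditions)
        if unknown:
            raise ValueError(f"planted effects name unknown conditions: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    targets: dict[str, list[str]]                   # miRNA -> target gene ids
    shared_targets: list[str]                       # targets of every planted miRNA
    site_positions: dict[str, dict[str, list[int]]]  # gene -> miRNA -> 0-based starts
    mirna_effects: pd.DataFrame                     # miRNA features x conditions
    mrna_effects: pd.DataFrame                      # mRNA features x conditions

    def n_sites(self, gene: str, mirna: str) -> int:
        return len(self.site_positions.get(gene, {}).get(mirna, []))


def _signature_blocks(cfg: SimulationConfig) -> list[tuple[str, dict[str, float]]]:
    """Per-condition signature profiles, one block per catabolic state.

    Den7/Den14 share a late-denervation block (the two denervation timepoints
    group together); STV24/STV48 share a starvation block; Den3 carries its own
    mild, mostly-down block; STZ a broadly up block; C26 a broadly down block.
    """
    s = cfg.signature_log2fc
    blocks = []
    cond = set(cfg.conditions)
    if {"Den7", "Den14"} <= cond:
        blocks.append(("den", {"Den7": s, "Den14": s}))
    if "Den3" in cond:
        blocks.append(("den3", {"Den3": -0.6 * s}))
    if {"STV24", "STV48"} <= cond:
        blocks.append(("stv", {"STV24": s, "STV48": s}))
    if "STZ" in cond:
        blocks.append(("stz", {"STZ": s}))
    if "C26" in cond:
        blocks.append(("c26", {"C26": -s}))
    return blocks


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Draw one synthetic study: miRNA matrix, mRNA matrix and ground truth.

    Non-planted features have zero expected log2 ratio; planted features follow
    their per-condition effects; i.i.d. Gaussian noise (``noise_sd``) is added
    on the log2 scale, and entries whose simulated log2 abundance falls below
    ``dropout_threshold`` are masked.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    conds = list(config.conditions)
    n_cond = len(conds)
    reps = config.replicates
    sample_ids = [f"{c}_r{r+1}" for c in conds for r in range(reps)]
    meta = {s: SampleMeta(condition=s.rsplit("_r", 1)[0],
                          timepoint=_TIMEPOINTS.get(s.rsplit("_r", 1)[0], 0.0))
            for s in sample_ids}
    cond_of_sample = np.repeat(np.arange(n_cond), reps)

    # ---- miRNA feature ids and effects
    planted_names = list(config.planted_mirnas)
    mirna_ids = list(planted_names)
    mirna_eff = np.zeros((config.n_mirna, n_cond))
    for i, name in enumerate(planted_names):
        for c, fc in config.planted_mirnas[name].items():
            mirna_eff[i, conds.index(c)] = fc
    if config.signature_mirnas_per_block > 0:
        for block, profile in _signature_blocks(config):
            for k in range(config.signature_mirnas_per_block):
                if len(mirna_ids) >= config.n_mirna:
                    break
                i = len(mirna_ids)
                mirna_ids.append(f"miR-sig-{block}-{k+1:02d}")
                sign = 1.0 if k % 2 == 0 else -1.0
                # blocks with a stated overall direction keep it; mixed blocks
                # alternate sign so signatures are not purely up
                if block in ("stz", "c26", "den3", "den"):
                    sign = 1.0
                for c, fc in profile.items():
                    mirna_eff[i, conds.index(c)] = sign * fc
    while len(mirna_ids) < config.n_mirna:
        mirna_ids.append(f"miR-bg-{len(mirna_ids)+1:03d}")

    # ---- mRNA feature ids, targets and effects
    n_shared = config.shared_targets
    n_unique = config.targets_per_mirna - n_shared
    gene_ids = [f"G{i+1:05d}" for i in range(config.n_mrna)]
    cursor = 0
    shared = gene_ids[cursor:cursor + n_shared]
    cursor += n_shared
    targets: dict[str, list[str]] = {}
    for name in planted_names:
        own = gene_ids[cursor:cursor + n_unique]
        cursor += n_unique
        targets[name] = list(shared) + own
    program = gene_ids[cursor:cursor + config.n_program_mrna]
    cursor += config.n_program_mrna

    mrna_eff = np.zeros((config.n_mrna, n_cond))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for name in planted_names:
        up = {c for c, fc in config.planted_mirnas[name].items() if fc > 0}
        for g in targets[name]:
            for c in up:
                mrna_eff[gene_index[g], conds.index(c)] += config.repression_log2fc
    # transcriptional atrophy program: peaks at Den3, decays by Den7/Den14
    if config.kinetic_shift and config.n_program_mrna > 0:
        decay = {"Den3": 1.0, "Den7": 0.3, "Den14": 0.1}
        for k, g in enumerate(program):
            sign = 1.0 if k % 2 == 0 else -1.0
            for c, w in decay.items():
                if c in conds:
                    mrna_eff[gene_index[g], conds.index(c)] = sign * w * config.program_log2fc

    truth = GroundTruth(
        targets=targets,
        shared_targets=list(shared),
        site_positions={},
        mirna_effects=pd.DataFrame(mirna_eff, index=mirna_ids, columns=conds),
        mrna_effects=pd.DataFrame(mrna_eff, index=gene_ids, columns=conds),
    )

    def build(ids: list[str], eff: np.ndarray, kind: str) -> ExpressionMatrix:
        n_feat = len(ids)
        values = eff[:, cond_of_sample] + rng.normal(0.0, config.noise_sd,
                                                     size=(n_feat, n_cond * reps))
        if config.noise_sd == 0.0:
            values = eff[:, cond_of_sample].copy()
        # detection is driven by per-spot log2 abundance: a per-feature
        # baseline plus the planted effect plus spot-level hybridization
        # variation (which largely cancels in the two-channel ratio, so it
        # enters the mask but not the reported value)
        baseline = rng.normal(config.abundance_mean, config.abundance_sd, size=n_feat)
        spot_noise = rng.normal(0.0, config.intensity_noise_sd, size=values.shape)
        abundance = baseline[:, None] + values + spot_noise
        mask = abundance < config.dropout_threshold
        values = np.where(mask, np.nan, values)
        return ExpressionMatrix(feature_ids=ids, sample_ids=list(sample_ids),
                                values=values, mask=mask, sample_meta=dict(meta),
                                value_kind="log_ratio")

    mirna_matrix = build(mirna_ids, mirna_eff, "mirna")
    mrna_matrix = build(gene_ids, mrna_eff, "mrna")
    return mirna_matrix, mrna_matrix, truth


# ---------------------------------------------------------------------------
# UTR simulation


def _seed_rc(mature: str, seed_span: tuple[int, int] = (1, 8)) -> str:
    """Reverse complement of the seed (mature positions 2-8), 5'->3' on the UTR."""
    seed = mature[seed_span[0]:seed_span[1]]
    return seed.translate(RNA_COMPLEMENT)[::-1]


def _count_matches(utr: str, motif: str) -> int:
    n, m, c = len(utr), len(motif), 0
    for i in range(n - m + 1):
        if utr[i:i + m] == motif:
            c += 1
    return c


def simulate_utrs(
    truth: GroundTruth,
    mirna_seqs: dict[str, str] | None = None,
    utr_length: int = 300,
    rng_seed: int = 0,
    max_tries: int = 200,
) -> dict[str, str]:
    """Generate a 3'UTR (RNA, 5'->3') per gene in the truth's mRNA universe.

    Planted targets receive exactly their planted number of exact
    seed-complement sites at recorded positions (written back into
    ``truth.site_positions``); all other positions — and the entirety of
    non-target UTRs — are rejection-sampled to contain zero seed matches for
    any planted miRNA.  Base composition is uniform otherwise.
    """
    if utr_length < 30:
        raise ValueError("utr_length must be >= 30")
    if mirna_seqs is None:
        mirna_seqs = {m: DEFAULT_MATURE_SEQS[m] for m in truth.targets}
    rng = np.random.default_rng(rng_seed)
    motifs = {m: _seed_rc(seq) for m, seq in mirna_seqs.items() if m in truth.targets}
    if not motifs:
        raise ValueError("no planted miRNA has a mature sequence")
    site_len = len(next(iter(motifs.values())))
    bases = np.array(list("ACGU"))

    # per-gene requested site counts (1..3 sites per planted target)
    requested: dict[str, dict[str, int]] = {}
    for mirna, genes in truth.targets.items():
        for g in genes:
            requested.setdefault(g, {})[mirna] = int(rng.integers(1, 4))

    def random_utr() -> str:
        return "".join(bases[rng.integers(0, 4, size=utr_length)])

    def clean(utr: str) -> bool:
        return all(_count_matches(utr, mo) == 0 for mo in motifs.values())

    utrs: dict[str, str] = {}
    truth.site_positions = {}
    for g in truth.mrna_effects.index:
        want = requested.get(g, {})
        n_sites = sum(want.values())
        if n_sites * site_len > utr_length - site_len:
            raise ValueError(
                f"utr_length={utr_length} too short for {n_sites} sites of "
                f"length {site_len} in gene {g}"
            )
        for _ in range(max_tries):
            utr = random_utr()
            if not want:
                if clean(utr):
                    utrs[g] = utr
                    break
                continue
            # plant sites at non-overlapping random positions
            slots = sorted(rng.choice(utr_length // site_len, size=n_sites,
                                      replace=False))
            positions = [s * site_len for s in slots]
            chars = list(utr)
            pos_by_mirna: dict[str, list[int]] = {}
            i = 0
            for mirna, k in want.items():
                for _ in range(k):
                    p = positions[i]
                    chars[p:p + site_len] = motifs[mirna]
                    pos_by_mirna.setdefault(mirna, []).append(p)
                    i += 1
            planted = "".join(chars)
            # exact-count check: planting must not create extra matches
            ok = all(_count_matches(planted, motifs[m]) == want.get(m, 0)
                     for m in motifs)
            if ok:
                utrs[g] = planted
                truth.site_positions[g] = {m: sorted(v) for m, v in pos_by_mirna.items()}
                break
        else:
            raise RuntimeError(f"could not sample a valid UTR for gene {g}")
    return utrs
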