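"""Seed-site scanning of 3'UTRs and thermodynamic site scoring.

A candidate site is a match of the reverse complement of the miRNA seed
(mature nucleotides 2-8) on the sense strand of a 3'UTR.  Each site gets a
net binding score ddG = dG_duplex - dG_open: the hybridization energy of the
seed duplex minus the cost of opening local target secondary structure to
make the site accessible (more negative = stronger predicted repression).
Per-gene scores aggregate all sites with a log-sum-exp reduction, so extra
sites always strengthen (never weaken) the total.

The duplex energy uses a pluggable nearest-neighbor-style stacking table; the
default table is a deliberately simplified stand-in (per Watson-Crick pair:
GC -3.0, AU -2.0, GU wobble -1.0; per adjacent pair of paired positions an
extra -2.0 stacking bonus).  dG_open backends are pluggable too: a null
backend (0 cost), a local AU-content proxy, and an optional RNA-folding
backend (ViennaRNA) when its bindings are importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.special import logsumexp

__all__ = [
    "MatureMiRNA", "TargetSite", "TargetPrediction",
    "extract_seed", "scan_sites", "score_site", "aggregate_score",
    "predict_targets", "DEFAULT_PAIR_ENERGY", "DEFAULT_STACK_BONUS",
    "null_open_energy", "au_content_open_energy", "vienna_open_energy",
]

RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

# simplified per-pair hybridization energies (dimensionless, kcal/mol-like)
DEFAULT_PAIR_ENERGY = {"GC": -3.0, "AU": -2.0, "GU": -1.0}
DEFAULT_STACK_BONUS = -2.0


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: name and 5'->3' RNA sequence (length 18-26)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.name}: sequence has non-ACGU characters")

    @property
    def seed(self) -> str:
        return extract_seed(self)


@dataclass
class TargetSite:
    """A seed-complement site on a UTR, 0-based half-open, sense strand.

    ``dG_open`` follows the accessibility-score sign convention: it is the
    free-energy difference (unconstrained ensemble minus ensemble with the
    site forced single-stranded), hence <= 0; its magnitude is the cost of
    opening the site.  ddG = dG_duplex - dG_open, so an inaccessible site
    (large opening cost) weakens the total.
    """

    gene_id: str
    mirna: str
    start: int
    end: int
    match_type: str = "7mer-exact"
    dG_duplex: float | None = None
    dG_open: float | None = None

    @property
    def opening_cost(self) -> float:
        """Nonnegative cost of making the site accessible."""
        if self.dG_open is None:
            raise ValueError("site has not been scored yet")
        return -self.dG_open

    @property
    def ddG(self) -> float:
        if self.dG_duplex is None or self.dG_open is None:
            raise ValueError("site has not been scored yet")
        return self.dG_duplex - self.dG_open


@dataclass
class TargetPrediction:
    gene_id: str
    mirna: str
    n_sites: int
    ddG_total: float
    sites: list[TargetSite] = field(default_factory=list)


def extract_seed(mirna: MatureMiRNA, start: int = 2, end: int = 8) -> str:
    """Seed = mature nucleotides ``start``..``end`` (1-based, inclusive)."""
    seq = mirna.sequence
    if len(seq) < end:
        raise ValueError(
            f"{mirna.name}: mature sequence of length {len(seq)} is too short "
            f"for a seed ending at position {end}"
        )
    return seq[start - 1:end]


def _pairs_match(site_nt: str, seed_nt: str, allow_gu: bool) -> bool:
    pair = (seed_nt, site_nt)
    return pair in _WC or (allow_gu and pair in _GU)


def scan_sites(
    utr: str,
    mirna: MatureMiRNA,
    policy: str = "7mer-exact",
) -> list[TargetSite]:
    """Find all seed-complement sites on the UTR sense strand.

    ``policy`` is one of ``7mer-exact`` (perfect Watson-Crick complement of
    the 7-nt seed, the default), ``7mer-1GU`` (additionally allow sites with
    exactly one G:U wobble pair), or ``6mer`` (perfect complement of seed
    nucleotides 2-7).  Overlapping sites are reported at distinct starts.
    """
    utr = utr.upper().replace("T", "U")
    seed = extract_seed(mirna)
    if policy == "6mer":
        seed = seed[:6]
    elif policy not in ("7mer-exact", "7mer-1GU"):
        raise ValueError(f"unknown scan policy {policy!r}")
    m = len(seed)
    # the seed (5'->3') pairs antiparallel to the UTR: UTR position start+j
    # pairs with seed position m-1-j
    rev_seed = seed[::-1]
    sites: list[TargetSite] = []
    for i in range(len(utr) - m + 1):
        window = utr[i:i + m]
        wobbles = 0
        ok = True
        for j in range(m):
            pair = (rev_seed[j], window[j])
            if pair in _WC:
                continue
            if policy == "7mer-1GU" and pair in _GU and wobbles == 0:
                wobbles += 1
                continue
            ok = False
            break
        if ok:
            mt = policy if policy != "7mer-1GU" else ("7mer-1GU" if wobbles else "7mer-exact")
            sites.append(TargetSite(gene_id="", mirna=mirna.name, start=i,
                                    end=i + m, match_type=mt))
    return sites


# ---------------------------------------------------------------------------
# energies


def duplex_energy(
    site_window: str,
    seed: str,
    pair_energy: dict[str, float] | None = None,
    stack_bonus: float = DEFAULT_STACK_BONUS,
) -> float:
    """Stacking-table duplex energy of a seed bound to its site window.

    Sums a per-pair increment for every paired position plus ``stack_bonus``
    for every adjacent pair of paired positions.  A simplified stand-in for a
    full nearest-neighbor model.
    """
    if pair_energy is None:
        pair_energy = DEFAULT_PAIR_ENERGY
    rev_seed = seed[::-1]
    if len(site_window) != len(seed):
        raise ValueError("site window and seed length differ")
    e = 0.0
    paired = []
    for j, (s_nt, u_nt) in enumerate(zip(rev_seed, site_window)):
        pair = (s_nt, u_nt)
        if pair in _WC:
            key = "GC" if s_nt in "GC" else "AU"
        elif pair in _GU:
            key = "GU"
        else:
            paired.append(False)
            continue
        e += pair_energy[key]
        paired.append(True)
    for j in range(1, len(paired)):
        if paired[j] and paired[j - 1]:
            e += stack_bonus
    return e


def null_open_energy(utr: str, start: int, end: int) -> float:
    """Null accessibility backend: opening the site costs nothing."""
    return 0.0


def au_content_open_energy(
    utr: str, start: int, end: int, flank: int = 15, scale: float = 5.0
) -> float:
    """AU-content proxy for accessibility: GC-rich flanks cost more to open.

    Returns scale * (GC fraction of the site plus ``flank`` nt on each side),
    a cheap monotone proxy for structure-opening cost (>= 0).
    """
    lo, hi = max(0, start - flank), min(len(utr), end + flank)
    window = utr[lo:hi]
    if not window:
        return 0.0
    gc = sum(1 for c in window if c in "GC") / len(window)
    return scale * gc


def vienna_open_energy(utr: str, start: int, end: int, flank: int = 15) -> float:
    """Ensemble opening cost from RNA folding (requires ViennaRNA bindings).

    dG_open = dG(unconstrained ensemble of the local window) minus dG of the
    ensemble constrained to keep the site single-stranded, negated to a
    nonnegative cost.
    """
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError("ViennaRNA python bindings are not installed") from exc
    lo, hi = max(0, start - 3 * flank), min(len(utr), end + 3 * flank)
    window = utr[lo:hi]
    fc = RNA.fold_compound(window)
    g_free = fc.pf()[1]
    fc2 = RNA.fold_compound(window)
    for pos in range(start - lo, end - lo):
        fc2.hc_add_up(pos + 1)  # 1-based
    g_open = fc2.pf()[1]
    return max(0.0, float(g_open - g_free))


def score_site(
    site: TargetSite,
    utr: str,
    mirna: MatureMiRNA,
    duplex_model=duplex_energy,
    open_model=null_open_energy,
) -> TargetSite:
    """Fill in dG_duplex and dG_open for a scanned site (ddG derives).

    ``open_model(utr, start, end)`` returns the nonnegative cost of opening
    the site; it is stored as ``dG_open = -cost`` per the sign convention of
    :class:`TargetSite`.
    """
    utr = utr.upper().replace("T", "U")
    if not (0 <= site.start < site.end <= len(utr)):
        raise ValueError(
            f"site [{site.start},{site.end}) outside UTR of length {len(utr)}"
        )
    seed = extract_seed(mirna)
    if site.match_type == "6mer":
        seed = seed[:6]
    window = utr[site.start:site.end]
    site.dG_duplex = float(duplex_model(window, seed))
    site.dG_open = -float(open_model(utr, site.start, site.end))
    return site


def aggregate_score(ddgs: list[float]) -> float:
    """Combine per-site ddG values: total = -ln(sum_i exp(-ddG_i)).

    A single site reduces to its own score; every extra site makes the total
    strictly more negative.  Computed with a shifted log-sum-exp so very
    negative scores do not overflow.
    """
    if not ddgs:
        raise ValueError("cannot aggregate an empty site list")
    return float(-logsumexp([-g for g in ddgs]))


def predict_targets(
    utrs: dict[str, str],
    mirnas: list[MatureMiRNA],
    cutoff: float = 0.0,
    policy: str = "7mer-exact",
    duplex_model=duplex_energy,
    open_model=null_open_energy,
) -> tuple[list[TargetPrediction], list[str]]:
    """Scan and score every (gene, miRNA) pair; keep ddG_total <= cutoff.

    Returns (predictions sorted by (gene, miRNA), genes whose UTR was missing
    or empty — recorded as unevaluated rather than silently skipped).
    """
    predictions: list[TargetPrediction] = []
    unevaluated = [g for g, u in utrs.items() if not u]
    for gene in sorted(utrs):
        utr = utrs[gene]
        if not utr:
            continue
        for mir in sorted(mirnas, key=lambda m: m.name):
            sites = scan_sites(utr, mir, policy=policy)
            if not sites:
                continue
            for s in sites:
                s.gene_id = gene
                score_site(s, utr, mir, duplex_model=duplex_model,
                           open_model=open_model)
            total = aggregate_score([s.ddG for s in sites])
            if total <= cutoff:
                predictions.append(
                    TargetPrediction(gene_id=gene, mirna=mir.name,
                                     n_sites=len(sites), ddG_total=total,
                                     sites=sites)
                )
    return predictions, unevaluated
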