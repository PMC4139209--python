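"""Readers/writers for every on-disk format the pipeline touches.

Expression matrices travel as UTF-8 TSV (first column = feature ids, header =
sample ids, "NA" or empty cell = missing, optional sidecar TSV with per-sample
condition/timepoint metadata).  Sequences travel as FASTA (via Biopython) and
gene sets as GMT.  The tables printed in the source study (cloning oligos,
DE summary, shared-target list, enrichment categories) ship with the package
as plain-TSV transcriptions and are exposed through :func:`load_fixture`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import ExpressionMatrix, SampleMeta

__all__ = [
    "SharedTargetRecord",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "load_fixture",
    "FIXTURE_NAMES",
]

NA_TOKENS = {"", "NA", "NaN", "nan"}

# Internal canonical alphabet is RNA; DNA input is converted on read.
_DNA2RNA = str.maketrans("Tt", "Uu")


@dataclass(frozen=True)
class SharedTargetRecord:
    """One row of the shared-target table: per-miRNA site count and score.

    Scores are aggregated ddG values (dimensionless energy score, more
    negative = stronger predicted repression); a miRNA with 0 sites for the
    gene has score None.
    """

    gene_symbol: str
    sites_206: int
    score_206: float | None
    sites_21: int
    score_21: float | None

    def __post_init__(self):
        for n, s in ((self.sites_206, self.score_206), (self.sites_21, self.score_21)):
            if n < 0:
                raise ValueError("site counts must be >= 0")
            if n == 0 and s is not None:
                raise ValueError("a record with 0 sites carries no score")


class GeneSetCollection:
    """term_id -> (term_name, frozenset of uppercased gene symbols)."""

    def __init__(self, sets: dict[str, tuple[str, frozenset[str]]]):
        for term, (_, members) in sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} has no members")
        self._sets = dict(sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __contains__(self, term: str) -> bool:
        return term in self._sets

    def name(self, term: str) -> str:
        return self._sets[term][0]

    def members(self, term: str) -> frozenset[str]:
        return self._sets[term][1]

    def items(self):
        return self._sets.items()

    @classmethod
    def from_dict(cls, d: dict[str, set[str]]) -> "GeneSetCollection":
        return cls({t: (t, frozenset(g.upper() for g in m)) for t, m in d.items()})


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    value_kind: str = "log_ratio",
    meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a features x samples TSV into an :class:`ExpressionMatrix`.

    First column holds feature ids, the header row sample ids; "NA" or empty
    cells mark below-detection values.  ``meta_path`` optionally points to a
    sidecar TSV with columns sample_id, condition, timepoint.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    n_cols = len(header)
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n_cols:
            raise ValueError(
                f"{path}:{ln_no}: ragged row ({len(cells)} cells, expected {n_cols})"
            )
        feature_ids.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:]):
            if cell in NA_TOKENS:
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at feature "
                        f"{cells[0]!r}, sample {sample_ids[j]!r}"
                    ) from None
        rows.append(row)
    dup = pd.Index(feature_ids)[pd.Index(feature_ids).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature ids: {dup}")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    meta: dict[str, SampleMeta] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str})
        for _, r in mdf.iterrows():
            meta[str(r["sample_id"])] = SampleMeta(
                condition=str(r["condition"]),
                timepoint=float(r.get("timepoint", 0.0)),
            )
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        sample_meta=meta,
        value_kind=value_kind,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    meta_path: str | Path | None = None,
    float_fmt: str = "%.10g",
) -> None:
    """Write the matrix as TSV; masked cells become "NA"."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            cells = [
                "NA" if matrix.mask[i, j] else float_fmt % matrix.values[i, j]
                for j in range(len(matrix.sample_ids))
            ]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")
    if meta_path is not None and matrix.sample_meta:
        with open(meta_path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tcondition\ttimepoint\n")
            for s in matrix.sample_ids:
                m = matrix.sample_meta.get(s, SampleMeta(condition=s))
                fh.write(f"{s}\t{m.condition}\t{m.timepoint:g}\n")


# ---------------------------------------------------------------------------
# FASTA / GMT


def read_fasta(path: str | Path, alphabet: str = "rna") -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict.

    Sequences are uppercased; with ``alphabet="rna"`` (the package-wide
    canonical form) any T is converted to U on read, with ``"dna"`` the
    sequence is kept as DNA.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            seq = seq.translate(_DNA2RNA).upper()
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")
    del width  # SeqIO wraps at 60; width kept for interface stability


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln_no, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            cells = ln.split("\t")
            if len(cells) < 3:
                raise ValueError(
                    f"{path}:{ln_no}: malformed GMT line (need term, "
                    "description and at least one gene)"
                )
            term, desc = cells[0], cells[1]
            members = frozenset(g.upper() for g in cells[2:] if g)
            if not members:
                raise ValueError(f"{path}:{ln_no}: gene set {term!r} has no members")
            sets[term] = (desc, members)
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in collection.items():
            fh.write("\t".join([term, desc] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures

FIXTURE_NAMES = (
    "table2_sequences",
    "table4_de_mirnas",
    "table5_shared_targets",
    "table6_categories",
)

# BLOCK-iT top-strand oligos embed the mature miRNA between a TGCTG prefix and
# the hairpin-loop linker.
_OLIGO_PREFIX = "TGCTG"
_OLIGO_LOOP = "GTTTTGGCCACTGAC"


def _fixture_path(name: str) -> Path:
    return Path(resources.files("atromir.data") / f"{name}.tsv")


def _read_fixture_tsv(name: str) -> pd.DataFrame:
    return pd.read_csv(_fixture_path(name), sep="\t", comment="#")


def mature_from_top_oligo(oligo_dna: str) -> str:
    """Extract the mature miRNA (as RNA) embedded in a BLOCK-iT top oligo."""
    s = oligo_dna.upper().replace(" ", "")
    if not s.startswith(_OLIGO_PREFIX):
        raise ValueError("top oligo does not start with the expected TGCTG prefix")
    end = s.find(_OLIGO_LOOP, len(_OLIGO_PREFIX))
    if end < 0:
        raise ValueError("top oligo does not contain the hairpin-loop linker")
    return s[len(_OLIGO_PREFIX):end].translate(_DNA2RNA)


def load_fixture(name: str):
    """Load one of the packaged in-study tables.

    * ``table2_sequences`` -> {miRNA name: mature RNA sequence} recovered from
      the cloning oligos.
    * ``table4_de_mirnas`` -> DataFrame of per-condition regulation calls.
    * ``table5_shared_targets`` -> list of :class:`SharedTargetRecord`.
    * ``table6_categories`` -> DataFrame (term_name, p_value, genes list).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    df = _read_fixture_tsv(name)
    if name == "table2_sequences":
        out: dict[str, str] = {}
        for _, r in df[df["role"] == "top"].iterrows():
            out[str(r["name"])] = mature_from_top_oligo(str(r["dna_sequence"]))
        return out
    if name == "table4_de_mirnas":
        return df
    if name == "table5_shared_targets":
        recs = []
        for _, r in df.iterrows():
            recs.append(
                SharedTargetRecord(
                    gene_symbol=str(r["gene_symbol"]),
                    sites_206=int(r["sites_206"]),
                    score_206=float(r["score_206"]),
                    sites_21=int(r["sites_21"]),
                    score_21=float(r["score_21"]),
                )
            )
        return recs
    # table6_categories
    df = df.copy()
    df["genes"] = df["genes"].map(lambda s: [g.strip().upper() for g in s.split(",")])
    return df
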