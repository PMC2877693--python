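"""Experiment tables and the error-weighted design matrix.

Each antisense experiment contributes one row: the 64 circular triplet
counts of its mRNA target (or 16 doublet counts under the nearest-neighbor
model), an indicator for the more sensitive cell line, and one indicator
per targeted gene.  Rows and the response (percent reduction in accumulated
protein) are divided by the per-experiment measurement error, so that
ordinary least squares on the weighted system is the chi-square fit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import (
    DOUBLETS,
    TRIPLETS,
    NucleotideSequence,
    antisense_complement,
)

EXPERIMENT_COLUMNS = ["id", "target", "cell", "gene", "reduction", "error"]


@dataclass(frozen=True)
class Experiment:
    """One antisense measurement.

    ``target`` is the mRNA target site 5'->3' (RNA alphabet); ``reduction``
    is the percent reduction in accumulated protein and ``error`` its
    standard error (%, strictly positive — the weighting is integral to the
    chi-square machinery, so rows without errors are rejected rather than
    imputed).
    """

    id: str
    target: NucleotideSequence
    cell: str
    gene: str
    reduction: float
    error: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.reduction):
            raise ValueError(f"experiment {self.id}: non-finite reduction")
        if not (np.isfinite(self.error) and self.error > 0):
            raise ValueError(f"experiment {self.id}: error must be > 0")


@dataclass
class DesignMatrix:
    """Error-weighted linear system ``matrix @ params = response``.

    ``matrix`` row h is (raw features of experiment h) / error_h and
    ``response[h]`` = reduction_h / error_h.  ``errors`` and ``reductions``
    keep the unweighted quantities for fitted-value reporting.
    """

    matrix: np.ndarray
    response: np.ndarray
    column_names: list[str]
    errors: np.ndarray
    reductions: np.ndarray
    experiment_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def unweighted(self) -> np.ndarray:
        return self.matrix * self.errors[:, None]


def _kmer_counts(target: NucleotideSequence, order: str) -> np.ndarray:
    from . import seqcore

    circ = target.circularized()
    if order == "triplet":
        return seqcore.count_triplets(circ)
    if order == "doublet":
        return seqcore.count_doublets(circ)
    raise ValueError(f"unknown model order {order!r}")


def build_design(
    experiments: list[Experiment],
    order: str = "triplet",
    cell_covariate: bool = True,
    gene_covariate: bool = True,
    sensitive_cell: str | None = None,
) -> DesignMatrix:
    """Assemble the weighted design matrix from an experiment table.

    Cell encoding follows the asymmetric scheme of the source analysis: a
    single indicator column per non-reference cell label, holding 1 for
    experiments in that line.  With two labels the column marks the
    ``sensitive_cell`` (default: lexicographically first label).  Gene
    encoding is one indicator column per gene, exactly one 1 per row, so
    the gene columns sum to the all-ones vector before weighting.
    112 experiments with the triplet model, one cell column and four genes
    give the canonical 112 x 69 layout.
    """
    if not experiments:
        raise ValueError("no experiments")
    kmers = TRIPLETS if order == "triplet" else DOUBLETS
    names: list[str] = list(kmers)

    cells = sorted({e.cell for e in experiments})
    genes = sorted({e.gene for e in experiments})

    cell_levels: list[str] = []
    if cell_covariate:
        if sensitive_cell is not None and sensitive_cell not in cells:
            raise ValueError(f"unknown cell label {sensitive_cell!r}")
        if len(cells) == 1:
            cell_levels = list(cells)
        elif len(cells) == 2:
            cell_levels = [sensitive_cell or cells[0]]
        else:
            # one indicator per non-reference level; reference = lexicographically
            # last so that with two labels the first (e.g. A549 < T24) gets the 1
            ref = cells[-1]
            cell_levels = [c for c in cells if c != ref]
        names += [f"cell:{c}" for c in cell_levels]
    if gene_covariate:
        names += [f"gene:{g}" for g in genes]

    n, k = len(experiments), len(names)
    raw = np.zeros((n, k), dtype=float)
    reductions = np.empty(n)
    errors = np.empty(n)
    ids = []
    for h, e in enumerate(experiments):
        raw[h, : len(kmers)] = _kmer_counts(e.target, order)
        if cell_covariate and e.cell in cell_levels:
            raw[h, names.index(f"cell:{e.cell}")] = 1.0
        if gene_covariate:
            raw[h, names.index(f"gene:{e.gene}")] = 1.0
        reductions[h] = e.reduction
        errors[h] = e.error
        ids.append(e.id)

    matrix = raw / errors[:, None]
    response = reductions / errors
    return DesignMatrix(matrix, response, names, errors, reductions, ids)


def _infer_sep(path) -> str:
    p = str(path)
    if p.endswith(".tsv") or p.endswith(".tab"):
        return "\t"
    return ","


def read_experiments(
    path,
    as_antisense: bool = False,
    sep: str | None = None,
) -> list[Experiment]:
    """Read an experiment table (CSV/TSV with header id,target,cell,gene,
    reduction,error).

    With ``as_antisense=True`` the target column holds the antisense
    oligomer 5'->3' (DNA or RNA letters); the stored target is its
    reverse-complement mRNA sequence.  Malformed rows are reported with
    their 1-based data row number.
    """
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    experiments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            seq = NucleotideSequence.from_string(
                str(row.target), topology="circular", alphabet="RNA"
            )
            if as_antisense:
                seq = antisense_complement(seq, output_alphabet="RNA")
            exp = Experiment(
                id=str(row.id),
                target=seq,
                cell=str(row.cell),
                gene=str(row.gene),
                reduction=float(row.reduction),
                error=float(row.error),
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: row {i}: {err}") from err
        experiments.append(exp)
    return experiments


def experiments_to_csv(experiments: list[Experiment], sep: str = ",") -> str:
    """Render an experiment table as delimited text (full float precision)."""
    import io

    buf = io.StringIO()
    w = csv.writer(buf, delimiter=sep, lineterminator="\n")
    w.writerow(EXPERIMENT_COLUMNS)
    for e in experiments:
        w.writerow(
            [e.id, e.target.as_rna().residues, e.cell, e.gene,
             repr(float(e.reduction)), repr(float(e.error))]
        )
    return buf.getvalue()


def write_experiments(experiments: list[Experiment], path, sep: str | None = None) -> None:
    """Write an experiment table; full float precision so read/write round-trips."""
    sep = sep or _infer_sep(path)
    with open(path, "w", newline="") as fh:
        fh.write(experiments_to_csv(experiments, sep=sep))
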