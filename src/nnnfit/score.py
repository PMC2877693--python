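"""Apply a fitted parameter table to sequences.

The predicted percent reduction in accumulated protein for a circular
target is the inner product of its 64 overlapping triplet counts with the
triplet inhibition parameters, plus optional cell-line and gene offsets.
Individual triplet parameters are not identifiable (except the four
homotrinucleotides), but any realizable sequence sum is, so scores are
unique even though the parameter table itself is one representative of an
equivalence class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqcore import (
    DOUBLETS,
    TRIPLETS,
    NucleotideSequence,
    count_doublets,
    count_triplets,
)
from .solver import DEFAULT_SV_RTOL, FitResult


@dataclass
class ParameterTable:
    """Named triplet and covariate inhibition parameters (%, +/- SE).

    ``covariance``, when present, is aligned to ``column_names`` (the 64
    triplets followed by the covariates) and enables exact error
    propagation for sequence scores; otherwise only a naive
    root-sum-of-squares approximation is available.
    """

    triplet_params: dict[str, float]
    triplet_se: dict[str, float] = field(default_factory=dict)
    covariate_params: dict[str, float] = field(default_factory=dict)
    covariate_se: dict[str, float] = field(default_factory=dict)
    covariance: np.ndarray | None = None
    column_names: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(TRIPLETS) - set(self.triplet_params)
        extra = set(self.triplet_params) - set(TRIPLETS)
        if missing or extra:
            raise ValueError(
                f"triplet table must have exactly the 64 triplets "
                f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
                if missing and extra
                else f"triplet table mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        for d in (self.triplet_se, self.covariate_se):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative SE for {k}")
        if not self.column_names:
            self.column_names = list(TRIPLETS) + sorted(self.covariate_params)
        if self.covariance is not None:
            m = len(self.column_names)
            if self.covariance.shape != (m, m):
                raise ValueError("covariance shape does not match column names")

    @property
    def triplet_vector(self) -> np.ndarray:
        return np.array([self.triplet_params[t] for t in TRIPLETS])

    @classmethod
    def from_fit(cls, fit: FitResult, provenance: str = "") -> "ParameterTable":
        names = fit.column_names
        tp, tse, cp, cse = {}, {}, {}, {}
        for name, p, se in zip(names, fit.parameters, fit.standard_errors):
            if name in TRIPLETS:
                tp[name] = float(p)
                tse[name] = float(se)
            else:
                cp[name] = float(p)
                cse[name] = float(se)
        return cls(
            triplet_params=tp,
            triplet_se=tse,
            covariate_params=cp,
            covariate_se=cse,
            covariance=fit.covariance.copy(),
            column_names=list(names),
            provenance=provenance,
        )


@dataclass
class SequenceScore:
    """Predicted percent reduction for one circular target."""

    id: str
    P: float
    SE: float | None = None
    se_kind: str | None = None   # "covariance" | "naive"
    components: dict[str, float] = field(default_factory=dict)


@dataclass
class IndependenceReport:
    """Linear-independence diagnosis of a set of circular sequences."""

    sequence_ids: list[str]
    n_rows: int
    n_columns: int
    rank: int
    smallest_nonzero_sv: float
    independent: bool
    dependency: dict[str, float] = field(default_factory=dict)

    @property
    def verdict(self) -> str:
        return "independent" if self.independent else "dependent"


def _weight_vector(table: ParameterTable, counts: np.ndarray, cell, gene) -> np.ndarray:
    w = np.zeros(len(table.column_names))
    for t, c in zip(TRIPLETS, counts):
        w[table.column_names.index(t)] = c
    if cell is not None:
        w[table.column_names.index(f"cell:{cell}")] = 1.0
    if gene is not None:
        w[table.column_names.index(f"gene:{gene}")] = 1.0
    return w


def score_sequence(
    table: ParameterTable,
    seq: NucleotideSequence,
    cell: str | None = None,
    gene: str | None = None,
    naive_se: bool = False,
) -> SequenceScore:
    """Predicted percent reduction for a circular target sequence.

    P = sum_t count(t) * P(t), plus the cell/gene offsets when labels are
    supplied (constant offsets do not affect relative rankings, so they may
    be omitted).  SE comes from the full covariance when the table carries
    one; with ``naive_se=True`` a root-sum-of-squares of component SEs is
    reported instead, explicitly labeled as an approximation.
    """
    counts = count_triplets(seq.circularized())
    P = float(counts @ table.triplet_vector)
    components = {t: counts[i] * table.triplet_params[t]
                  for i, t in enumerate(TRIPLETS) if counts[i]}
    for kind, label in (("cell", cell), ("gene", gene)):
        if label is not None:
            key = f"{kind}:{label}"
            if key not in table.covariate_params:
                raise KeyError(f"unknown {kind} label {label!r}")
            P += table.covariate_params[key]
            components[key] = table.covariate_params[key]

    se: float | None = None
    se_kind: str | None = None
    if table.covariance is not None:
        w = _weight_vector(table, counts, cell, gene)
        se = float(np.sqrt(max(w @ table.covariance @ w, 0.0)))
        se_kind = "covariance"
    elif naive_se and table.triplet_se:
        var = sum((counts[i] * table.triplet_se[t]) ** 2 for i, t in enumerate(TRIPLETS))
        for kind, label in (("cell", cell), ("gene", gene)):
            if label is not None:
                var += table.covariate_se.get(f"{kind}:{label}", 0.0) ** 2
        se = math.sqrt(var)
        se_kind = "naive"
    return SequenceScore(id=seq.id, P=P, SE=se, se_kind=se_kind, components=components)


def scan_windows(
    table: ParameterTable,
    mrna: NucleotideSequence,
    window: int = 20,
    cell: str | None = None,
    gene: str | None = None,
) -> list[tuple[int, NucleotideSequence, SequenceScore]]:
    """Score every length-``window`` window of a linear mRNA, ranked by P.

    Each window is circularized before counting (the closed-circle
    convention keeps window scores commensurate with fitted parameters).
    Returns (start, window sequence, score) sorted by P descending, ties
    broken by ascending start; coordinates are 0-based half-open.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    rna = mrna.as_rna()
    if len(rna) < window:
        raise ValueError(f"sequence length {len(rna)} < window {window}")
    results = []
    for start in range(len(rna) - window + 1):
        sub = NucleotideSequence(
            rna.residues[start : start + window],
            topology="circular",
            id=f"{rna.id or 'seq'}:{start}-{start + window}",
        )
        results.append((start, sub, score_sequence(table, sub, cell=cell, gene=gene)))
    results.sort(key=lambda rec: (-rec[2].P, rec[0]))
    return results


def check_independence(
    sequences: list[NucleotideSequence], sv_rel_tolerance: float = DEFAULT_SV_RTOL
) -> IndependenceReport:
    """Test whether circular sequences have linearly independent triplet
    count vectors.

    Builds the 64 x m count matrix and ranks it by SVD.  At most 49
    sequences can be independent (the count space has dimension 49).  For a
    dependent set, one dependency is read off the null-space right singular
    vector with the smallest singular value.
    """
    if not sequences:
        raise ValueError("no sequences")
    ids = [s.id or s.residues for s in sequences]
    M = np.column_stack([count_triplets(s.circularized()) for s in sequences]).astype(float)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int((s > sv_rel_tolerance * s[0]).sum())
    independent = rank == len(sequences)
    dependency: dict[str, float] = {}
    if not independent:
        v = Vt[-1]
        v = v / np.max(np.abs(v))
        dependency = {ids[j]: float(v[j]) for j in range(len(ids)) if abs(v[j]) > 1e-9}
    nonzero = s[s > sv_rel_tolerance * s[0]]
    return IndependenceReport(
        sequence_ids=ids,
        n_rows=M.shape[0],
        n_columns=M.shape[1],
        rank=rank,
        smallest_nonzero_sv=float(nonzero[-1]) if len(nonzero) else 0.0,
        independent=independent,
        dependency=dependency,
    )


def is_estimable(design_or_space, combination: np.ndarray, tol: float = 1e-8) -> bool:
    """Whether a parameter combination is uniquely determined by the data.

    A combination w'P is estimable iff w lies in the row space of the
    design (equivalently, of the space spanned by realizable count/covariate
    rows).  Accepts a DesignMatrix, a FitResult, or a 2-D array whose rows
    span the space.  The zero vector is trivially estimable.
    """
    from .design import DesignMatrix

    if isinstance(design_or_space, DesignMatrix):
        rows = np.asarray(design_or_space.matrix, dtype=float)
    elif isinstance(design_or_space, FitResult):
        rows = np.asarray(design_or_space.row_space, dtype=float)
    else:
        rows = np.asarray(design_or_space, dtype=float)
    w = np.asarray(combination, dtype=float)
    if rows.ndim != 2 or w.shape != (rows.shape[1],):
        raise ValueError("combination length does not match design columns")
    wn = np.linalg.norm(w)
    if wn == 0:
        return True
    U, s, Vt = np.linalg.svd(rows, full_matrices=False)
    Vr = Vt[s > max(tol, DEFAULT_SV_RTOL) * s[0]]
    resid = w - Vr.T @ (Vr @ w)
    return bool(np.linalg.norm(resid) <= 1e-6 * wn)


def gene_minus_average(table: ParameterTable) -> dict[str, tuple[float, float | None]]:
    """Express gene offsets as differences from the gene average.

    Raw gene parameters are not individually estimable (their indicator
    columns sum to one), but differences from the average are.  Returns
    {gene: (offset, SE or None)}; offsets sum to zero.  SEs are propagated
    through the full covariance when the table carries one.
    """
    genes = sorted(k for k in table.covariate_params if k.startswith("gene:"))
    if len(genes) < 2:
        raise ValueError("need at least two gene parameters")
    vals = np.array([table.covariate_params[g] for g in genes])
    mean = vals.mean()
    out: dict[str, tuple[float, float | None]] = {}
    for i, g in enumerate(genes):
        se: float | None = None
        if table.covariance is not None:
            w = np.zeros(len(table.column_names))
            for j, g2 in enumerate(genes):
                w[table.column_names.index(g2)] = (1.0 if i == j else 0.0) - 1.0 / len(genes)
            se = float(np.sqrt(max(w @ table.covariance @ w, 0.0)))
        out[g.removeprefix("gene:")] = (float(vals[i] - mean), se)
    return out


def nn_free_energy(seq: NucleotideSequence, nn_table: dict[str, float]) -> float:
    """Total nearest-neighbor free energy of a circular target (kcal/mol).

    Inner product of the 16 circular doublet counts with a user-supplied
    doublet -> deltaG(37 C) map (e.g. in vitro DNA:RNA hybrid parameters).
    The table must cover all 16 doublets.
    """
    missing = set(DOUBLETS) - set(nn_table)
    if missing:
        raise KeyError(f"nn_table missing doublets: {sorted(missing)}")
    counts = count_doublets(seq.circularized())
    return float(sum(counts[i] * nn_table[d] for i, d in enumerate(DOUBLETS)))
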