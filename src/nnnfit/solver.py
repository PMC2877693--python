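"""Rank-deficient weighted least squares by singular value decomposition.

The triplet design is structurally singular: circular count vectors obey 15
flow-balance constraints and the gene indicators sum to one, so a design
with 64 triplet columns, one cell column and four gene columns has exactly
16 zero singular values.  The solver zeroes singular values below a
relative threshold, returns the minimum-norm solution, and builds the
parameter covariance from the retained modes only,

    cov = sum_i  v_i v_i^T / s_i^2 ,

so that only estimable combinations of parameters carry unique standard
errors.  Goodness of fit is the upper-tail probability Q of the observed
chi-square at dof = n_experiments - effective rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import DesignMatrix, Experiment, build_design

DEFAULT_SV_RTOL = 1e-8


@dataclass
class FitResult:
    """Solution of the weighted system with its uncertainty bookkeeping."""

    parameters: np.ndarray          # % units, aligned to column_names
    covariance: np.ndarray          # %^2
    standard_errors: np.ndarray     # %
    singular_values: np.ndarray     # non-increasing
    effective_rank: int
    zero_sv_count: int
    chi2: float
    dof: int
    q_value: float                  # NaN when dof <= 0
    fitted: np.ndarray              # unweighted predicted reductions (%)
    pearson_r: float
    column_names: list[str] = field(default_factory=list)
    null_space: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    row_space: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def parameter(self, name: str) -> tuple[float, float]:
        j = self.column_names.index(name)
        return float(self.parameters[j]), float(self.standard_errors[j])


def goodness_of_fit(chi2: float, dof: int) -> float:
    """Probability Q that a chi-square with ``dof`` degrees of freedom
    exceeds the observed value; Q > 0.1 is conventionally an adequate fit.

    Q is the regularized upper incomplete gamma function at (dof/2, chi2/2);
    it is 1 at chi2 = 0 and strictly decreasing in chi2.
    """
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return float(special.gammaincc(dof / 2.0, chi2 / 2.0))


def svd_fit(design: DesignMatrix, sv_rel_tolerance: float = DEFAULT_SV_RTOL) -> FitResult:
    """Minimum-norm weighted least squares with explicit zero-SV handling.

    Singular values below ``sv_rel_tolerance`` times the largest are
    treated as exact zeros: their reciprocals are excluded from both the
    solution and the covariance.  chi-square is the residual sum of squares
    of the weighted system; dof counts only the retained (estimable) modes.
    """
    if not (0 < sv_rel_tolerance < 1):
        raise ValueError("sv_rel_tolerance must be in (0, 1)")
    A = np.asarray(design.matrix, dtype=float)
    b = np.asarray(design.response, dtype=float)
    n, k = A.shape
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    keep = s > sv_rel_tolerance * s[0]
    rank = int(keep.sum())
    if rank == 0:
        raise ValueError("degenerate design: all singular values below threshold")

    inv_s = np.where(keep, 1.0, 0.0) / np.where(keep, s, 1.0)
    params = Vt.T @ (inv_s * (U.T @ b))
    V_keep = Vt[keep]                       # rank x k
    covariance = (V_keep.T * inv_s[keep] ** 2) @ V_keep
    standard_errors = np.sqrt(np.clip(np.diag(covariance), 0.0, None))

    resid = b - A @ params
    chi2 = float(resid @ resid)
    dof = n - rank
    q = goodness_of_fit(chi2, dof) if dof >= 1 else float("nan")

    fitted = (A @ params) * design.errors   # back to unweighted % scale
    obs = design.reductions
    if n >= 2 and np.std(fitted) > 0 and np.std(obs) > 0:
        r = float(stats.pearsonr(obs, fitted).statistic)
    else:
        r = float("nan")

    return FitResult(
        parameters=params,
        covariance=covariance,
        standard_errors=standard_errors,
        singular_values=s,
        effective_rank=rank,
        zero_sv_count=k - rank,
        chi2=chi2,
        dof=dof,
        q_value=q,
        fitted=fitted,
        pearson_r=r,
        column_names=list(design.column_names),
        null_space=Vt[~keep],
        row_space=V_keep,
    )


def propagate_error(fit: FitResult, combination: np.ndarray) -> float:
    """Standard error of the linear combination w'P via w' cov w.

    For a unit vector on column j this is that column's standard error.
    Unique only for estimable combinations (those in the design row space).
    """
    w = np.asarray(combination, dtype=float)
    if w.shape != (fit.covariance.shape[0],):
        raise ValueError(
            f"combination has length {w.shape}, expected {fit.covariance.shape[0]}"
        )
    var = float(w @ fit.covariance @ w)
    return float(np.sqrt(max(var, 0.0)))


def compare_models(
    experiments: list[Experiment],
    models: list[tuple[str, bool, bool]],
    sv_rel_tolerance: float = DEFAULT_SV_RTOL,
) -> pd.DataFrame:
    """Fit several model variants to the same experiments.

    ``models`` lists (order, cell_covariate, gene_covariate) triples, e.g.
    ("triplet", True, True) vs ("doublet", True, True).  Returns one row
    per model with effective rank, chi2, dof and Q for side-by-side
    goodness-of-fit comparison.
    """
    if len(models) < 2:
        raise ValueError("need at least two model specifications to compare")
    rows = []
    for order, cell_cov, gene_cov in models:
        dm = build_design(
            experiments, order=order, cell_covariate=cell_cov, gene_covariate=gene_cov
        )
        fit = svd_fit(dm, sv_rel_tolerance)
        rows.append(
            {
                "model": order,
                "cell_covariate": cell_cov,
                "gene_covariate": gene_cov,
                "n_columns": dm.shape[1],
                "effective_rank": fit.effective_rank,
                "zero_sv_count": fit.zero_sv_count,
                "chi2": fit.chi2,
                "dof": fit.dof,
                "Q": fit.q_value,
                "pearson_r": fit.pearson_r,
            }
        )
    return pd.DataFrame(rows)


def write_report(fit: FitResult, path, include_covariance: bool = False, header: str = "") -> None:
    """Serialize a fit to a structured-text report (12 significant digits)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# chi2 {fit.chi2:.12g}\n")
        fh.write(f"# dof {fit.dof}\n")
        fh.write(f"# Q {fit.q_value:.12g}\n")
        fh.write(f"# effective_rank {fit.effective_rank}\n")
        fh.write(f"# zero_sv_count {fit.zero_sv_count}\n")
        fh.write(f"# pearson_r {fit.pearson_r:.12g}\n")
        fh.write("[parameters]\n")
        for name, p, se in zip(fit.column_names, fit.parameters, fit.standard_errors):
            fh.write(f"{name}\t{p:.12g}\t{se:.12g}\n")
        fh.write("[singular_values]\n")
        for s in fit.singular_values:
            fh.write(f"{s:.12g}\n")
        if include_covariance:
            fh.write("[covariance]\n")
            for row in fit.covariance:
                fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
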