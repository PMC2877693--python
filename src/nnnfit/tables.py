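"""Parameter-table serialization and packaged reference data.

The package ships two small text fixtures: the published set of 64 triplet
inhibition parameters (with cell-line and gene covariates) fitted to 112
antisense S-DNA experiments across two human cell lines and four gene
targets, and the companion list of 49 circular 12-mers whose triplet count
vectors form a maximal linearly independent set.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .score import ParameterTable
from .seqcore import NucleotideSequence, TRIPLETS


def save_parameter_table(table: ParameterTable, path, include_covariance: bool = True) -> None:
    """Write a parameter table as structured text (sections: triplets,
    covariates, optional covariance aligned to triplets + sorted covariates)."""
    with open(path, "w") as fh:
        for line in (table.provenance or "").strip().splitlines():
            fh.write(f"# {line}\n")
        fh.write("[triplets]\n")
        for t in TRIPLETS:
            se = table.triplet_se.get(t, float("nan"))
            fh.write(f"{t}\t{table.triplet_params[t]:.12g}\t{se:.12g}\n")
        if table.covariate_params:
            fh.write("[covariates]\n")
            for name in sorted(table.covariate_params):
                se = table.covariate_se.get(name, float("nan"))
                fh.write(f"{name}\t{table.covariate_params[name]:.12g}\t{se:.12g}\n")
        if include_covariance and table.covariance is not None:
            fh.write("[covariance]\n")
            fh.write("# columns: " + " ".join(table.column_names) + "\n")
            for row in table.covariance:
                fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def _parse_parameter_text(text: str, provenance: str = "") -> ParameterTable:
    tp: dict[str, float] = {}
    tse: dict[str, float] = {}
    cp: dict[str, float] = {}
    cse: dict[str, float] = {}
    cov_rows: list[list[float]] = []
    section = None
    header_comments: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if section is None:
                header_comments.append(line.lstrip("# "))
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        if section == "triplets":
            name, val, se = line.split()
            tp[name] = float(val)
            if se.lower() != "nan":
                tse[name] = float(se)
        elif section == "covariates":
            name, val, se = line.split()
            cp[name] = float(val)
            if se.lower() != "nan":
                cse[name] = float(se)
        elif section == "covariance":
            cov_rows.append([float(v) for v in line.split()])
        else:
            raise ValueError(f"line outside a recognized section: {line!r}")
    cov = np.array(cov_rows) if cov_rows else None
    return ParameterTable(
        triplet_params=tp,
        triplet_se=tse,
        covariate_params=cp,
        covariate_se=cse,
        covariance=cov,
        provenance=provenance or "\n".join(header_comments),
    )


def load_parameter_table(path) -> ParameterTable:
    with open(path) as fh:
        return _parse_parameter_text(fh.read())


def reference_table() -> ParameterTable:
    """The packaged reference parameter set (printed two-decimal values).

    Derived from 112 antisense S-DNA inhibition experiments (CRAF1, BCL2,
    AKT2, PKC-alpha targets; A549 and T24 cells).  No covariance matrix is
    published for it, so scores from this table carry naive SEs at best.
    """
    text = resources.files("nnnfit.data").joinpath("reference_params.txt").read_text()
    return _parse_parameter_text(text)


def reference_independent_sequences() -> list[NucleotideSequence]:
    """The packaged set of 49 circular 12-mers with linearly independent
    triplet count vectors (4 homopolymers, 6 dinucleotide repeats, 20
    trinucleotide repeats, 19 tetranucleotide repeats)."""
    text = resources.files("nnnfit.data").joinpath("independent_12mers.txt").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, seq = line.split()
        out.append(NucleotideSequence(seq, topology="circular", id=name))
    return out
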