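"""cAMP dose-response profiles from a normalized log2 expression matrix.

The experiment behind this module exposes E. coli cells (a cyaA/tolC
double mutant that neither makes nor exports cAMP) to an external cAMP
dose series 0, 0.01, 0.03, 0.1, 0.3, 1, 3, 10 mM, in duplicate, and
measures genome-wide expression.  The matrix arriving here is already
background-corrected and normalized to the log2 scale (RMA upstream, out
of scope).  For each gene, replicates are averaged on the log2 scale per
dose and the zero-dose mean is subtracted, giving a log2 fold-change
profile over the positive doses.  Genes whose profile never reaches
0.5 log2 units in absolute value are considered unresponsive to cAMP and
filtered out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DOSE_GRID",
    "ExpressionMatrix",
    "DoseResponseProfile",
    "parse_sample_label",
    "read_matrix",
    "compute_profiles",
    "filter_responsive",
    "write_profiles",
]

#: cAMP dose grid (mM) used throughout, zero-dose control first.
DOSE_GRID: tuple[float, ...] = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)

_LABEL_RE = re.compile(r"^(?P<dose>\d+(?:\.\d+)?)\s*mM(?:_r(?P<rep>\d+))?$", re.IGNORECASE)


class MatrixValidationError(ValueError):
    """Expression matrix that violates the input contract."""


def parse_sample_label(label: str) -> tuple[float, int]:
    """Parse a column label like ``0.3mM_r2`` into (dose, replicate)."""
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise MatrixValidationError(f"cannot parse dose from sample label {label!r}")
    return float(m.group("dose")), int(m.group("rep") or 1)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression values over the dose grid.

    ``samples`` holds one (dose, replicate) pair per column of ``values``.
    """

    genes: list[str]
    samples: list[tuple[float, int]]
    values: np.ndarray  # shape (n_genes, n_samples), log2 scale

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise MatrixValidationError("values shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            dup = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise MatrixValidationError(f"duplicate gene rows: {dup}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"missing/non-finite value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]}"
            )
        if not any(d == 0.0 for d, _ in self.samples):
            raise MatrixValidationError("no zero-dose control column")

    @property
    def doses(self) -> list[float]:
        """Distinct doses, ascending (zero-dose control included)."""
        return sorted({d for d, _ in self.samples})


@dataclass
class DoseResponseProfile:
    """Per-gene log2 fold-change vs zero-dose control over the positive doses."""

    gene: str
    doses: tuple[float, ...]
    log2fc: np.ndarray

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if len(self.doses) != self.log2fc.size:
            raise ValueError("doses and log2fc length mismatch")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if not np.isfinite(self.log2fc).all():
            raise ValueError("log2fc must be finite")

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.log2fc).max())


def read_matrix(
    path: str | Path,
    *,
    dose_grid: tuple[float, ...] | None = DOSE_GRID,
) -> ExpressionMatrix:
    """Read a CSV/TSV expression matrix (first column gene ids, headers like ``1mM_r2``).

    With ``dose_grid`` given, every parsed dose must belong to it; pass
    ``None`` to accept any grid.  Delimiter is sniffed from the extension
    (.csv -> comma, else tab).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    samples = [parse_sample_label(str(c)) for c in df.columns]
    if dose_grid is not None:
        allowed = set(dose_grid)
        for (d, _r), col in zip(samples, df.columns):
            if d not in allowed:
                raise MatrixValidationError(
                    f"column {col!r}: dose {d} mM not on the declared grid {sorted(allowed)}"
                )
    return ExpressionMatrix(
        genes=[str(g) for g in df.index], samples=samples, values=df.to_numpy(float)
    )


def compute_profiles(m: ExpressionMatrix) -> list[DoseResponseProfile]:
    """Average replicates per dose on the log2 scale; subtract the zero-dose mean."""
    doses = m.doses
    pos = tuple(d for d in doses if d > 0)
    cols_at = {d: [j for j, (dd, _r) in enumerate(m.samples) if dd == d] for d in doses}
    means = {d: m.values[:, cols_at[d]].mean(axis=1) for d in doses}
    baseline = means[0.0]
    fc = np.column_stack([means[d] - baseline for d in pos])
    return [DoseResponseProfile(g, pos, fc[i]) for i, g in enumerate(m.genes)]


def filter_responsive(
    profiles: list[DoseResponseProfile],
    threshold: float = 0.5,
    mode: str = "any",
) -> tuple[list[DoseResponseProfile], list[DoseResponseProfile]]:
    """Split profiles into (kept, dropped) by the absolute log2 fold-change filter.

    ``mode='any'`` (default) keeps a gene when at least one dose reaches
    ``|log2fc| >= threshold`` — i.e. a gene is dropped only when every
    dose stays below.  ``mode='all'`` requires every dose to reach the
    threshold.  The boundary value counts as responsive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mode not in {"any", "all"}:
        raise ValueError("mode must be 'any' or 'all'")
    kept, dropped = [], []
    for p in profiles:
        hits = np.abs(p.log2fc) >= threshold
        ok = hits.any() if mode == "any" else hits.all()
        (kept if ok else dropped).append(p)
    return kept, dropped


def write_profiles(profiles: list[DoseResponseProfile], path: str | Path) -> None:
    """Profile table TSV: gene, one log2FC column per positive dose."""
    if not profiles:
        Path(path).write_text("gene\n")
        return
    doses = profiles[0].doses
    df = pd.DataFrame(
        [p.log2fc for p in profiles],
        index=pd.Index([p.gene for p in profiles], name="gene"),
        columns=[f"{d:g}mM" for d in doses],
    )
    df.to_csv(path, sep="\t", float_format="%.6g")
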