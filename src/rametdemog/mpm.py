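"""Stage-structured matrix population models.

Annual 6x6 projection matrices over (Sd, SR, MR, SF, MF, IA) are built
from three components: survival transitions (the product-reconstructed
unconditional probabilities, column sums <= 1), fecundity (seedlings at
t+1 per flowering ramet at t, entering row Sd from columns SF and MF),
and anonymous sprout recruitment (per-capita rates entering rows
SR/MR/SF/MF from the taproot-proxy columns SR, MR and IA).  The
asymptotic growth rate is the spectral radius; the stable stage
distribution is the dominant right eigenvector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from rametdemog.census import STAGES

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}
#: Columns credited with producing anonymous taproot sprouts.
DEFAULT_SPROUT_COLUMNS = ("SR", "MR", "IA")


class MPMError(ValueError):
    pass


@dataclass
class ProjectionMatrix:
    """An annual projection matrix and its labelled components.

    ``A = survival + fecundity + recruitment``; the partition matters
    because only the survival part is bounded by column sums <= 1 and
    by monocarpy (zero survival out of SF and MF).
    """

    site: str
    year: int | None
    survival: np.ndarray
    fecundity: np.ndarray
    recruitment: np.ndarray
    sprout_columns: tuple = DEFAULT_SPROUT_COLUMNS

    A: np.ndarray = field(init=False)

    def __post_init__(self):
        for name in ("survival", "fecundity", "recruitment"):
            m = getattr(self, name)
            if m.shape != (6, 6):
                raise MPMError(f"{name} component is not 6x6")
            if not np.all(np.isfinite(m)):
                raise MPMError(f"{name} component has non-finite entries")
            if (m < 0).any():
                raise MPMError(f"{name} component has negative entries")
        colsum = self.survival.sum(axis=0)
        for s in ("SF", "MF"):
            if colsum[STAGE_INDEX[s]] > 1e-10:
                raise MPMError(f"column {s} has survival transitions "
                               "(monocarpic ramets die after flowering)")
        bad = np.where(colsum > 1.0 + 1e-10)[0]
        if bad.size:
            raise MPMError(f"survival column sums exceed 1 for stage(s) "
                           f"{[STAGES[i] for i in bad]}")
        self.A = self.survival + self.fecundity + self.recruitment

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=list(STAGES), columns=list(STAGES))


def build_annual_matrix(rates: dict, site: str = "", year: int | None = None,
                        sprout_columns=DEFAULT_SPROUT_COLUMNS
                        ) -> ProjectionMatrix:
    """Assemble one annual matrix from a year's vital-rate estimates.

    ``rates`` maps parameter names (``<origin>_to_<fate>``, ``f``,
    ``<stage>_rec``) to values, as produced by
    :func:`rametdemog.vital_rates.assemble_vital_rates`.  Sprout
    recruitment rates are per capita of the pooled sprout columns, so
    each rate is added to every contributing column.
    """
    U = np.zeros((6, 6))
    F = np.zeros((6, 6))
    R = np.zeros((6, 6))
    for name, value in rates.items():
        if "_to_" in name:
            origin, fate = name.split("_to_")
            if origin in STAGE_INDEX and fate in STAGE_INDEX:
                U[STAGE_INDEX[fate], STAGE_INDEX[origin]] = value
    f = rates.get("f", 0.0)
    F[STAGE_INDEX["Sd"], STAGE_INDEX["SF"]] = f
    F[STAGE_INDEX["Sd"], STAGE_INDEX["MF"]] = f
    for cls in ("SR_rec", "MR_rec", "SF_rec", "MF_rec"):
        r = rates.get(cls, 0.0)
        row = STAGE_INDEX[cls[:2]]
        for col in sprout_columns:
            R[row, STAGE_INDEX[col]] = r
    return ProjectionMatrix(site=site, year=year, survival=U, fecundity=F,
                            recruitment=R, sprout_columns=tuple(sprout_columns))


def asymptotic_lambda(A, tol: float = 1e-12, max_iter: int = 10_000) -> float:
    """Spectral radius of a nonnegative matrix (dominant eigenvalue).

    Power iteration with an eigendecomposition fallback when the
    iteration stalls (e.g. equal-modulus complex pairs).
    """
    A = _as_matrix(A)
    if not np.all(np.isfinite(A)):
        raise MPMError("matrix has non-finite entries")
    if (A < 0).any():
        raise MPMError("matrix has negative entries")
    n = A.shape[0]
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        w = A @ v
        s = w.sum()
        if s <= 0:
            return 0.0
        w /= s
        if abs(s - lam) < tol * max(1.0, abs(s)) and np.allclose(w, v, atol=tol):
            return float(s)
        v, lam = w, s
    return float(np.max(np.abs(linalg.eigvals(A))))


def stable_stage_distribution(A, strict: bool = False) -> np.ndarray:
    """Dominant right eigenvector, normalized to proportions.

    If the dominant eigenspace is ambiguous (repeated dominant
    eigenvalue, e.g. a reducible matrix), a uniform distribution over
    the stages with nonzero rows is returned with a warning, or an
    error advising use of the mean matrix when ``strict=True``.
    """
    A = _as_matrix(A)
    vals, vecs = linalg.eig(A)
    lam = np.abs(vals).max()
    # the Perron root of a nonnegative matrix is the real eigenvalue
    # equal to the spectral radius; ambiguity means that root itself is
    # repeated (e.g. a reducible matrix), not that some other
    # eigenvalue merely shares its modulus (periodic cycles)
    dominant = np.where(np.abs(vals - lam) < 1e-9 * max(lam, 1.0))[0]
    if dominant.size == 0:
        dominant = np.where(np.abs(vals) > lam - 1e-9 * max(lam, 1.0))[0]
    if len(dominant) > 1:
        msg = ("dominant eigenvalue is not unique; the stable stage "
               "distribution is ambiguous — consider the mean matrix")
        if strict:
            raise MPMError(msg)
        warnings.warn(msg)
        support = A.sum(axis=1) > 0
        w = support.astype(float)
        return w / w.sum()
    w = np.real(vecs[:, dominant[0]])
    if np.all(w <= 1e-12):
        w = -w
    if (w < -1e-8 * max(1.0, np.abs(w).max())).any():
        raise MPMError("dominant eigenvector has mixed signs; matrix is "
                       "reducible — use the mean matrix")
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def transient_growth(n_t: float, n_t1: float, mode: str = "exp_relative") -> float:
    """Observed year-over-year growth from consecutive census totals.

    ``exp_relative`` is exp((N_{t+1} - N_t) / N_t); ``ratio`` is the
    plain N_{t+1} / N_t.  The two agree to second order for small
    changes.
    """
    if n_t <= 0:
        raise MPMError("transient growth undefined for N_t <= 0")
    if mode == "exp_relative":
        return float(np.exp((n_t1 - n_t) / n_t))
    if mode == "ratio":
        return float(n_t1 / n_t)
    raise MPMError(f"unknown mode {mode!r}")


def mean_matrix(matrices) -> ProjectionMatrix:
    """Elementwise arithmetic mean of annual matrices from one site."""
    matrices = list(matrices)
    if not matrices:
        raise MPMError("no matrices to average")
    sites = {m.site for m in matrices}
    if len(sites) > 1:
        raise MPMError(f"cannot average matrices across sites {sorted(sites)}")
    k = len(matrices)
    return ProjectionMatrix(
        site=matrices[0].site, year=None,
        survival=sum(m.survival for m in matrices) / k,
        fecundity=sum(m.fecundity for m in matrices) / k,
        recruitment=sum(m.recruitment for m in matrices) / k,
        sprout_columns=matrices[0].sprout_columns)


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, ProjectionMatrix):
        return A.A
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MPMError("expected a square matrix")
    return A
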