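"""Dose realizations and the Var(X|W) dose-uncertainty model.

A complex dosimetry system emits L joint realizations of cohort dose,
interpretable as draws from f(X|W), the distribution of true dose X given
everything known (W) about the dose determinants.  This module ingests such
realization matrices -- or point doses plus a CV/correlation specification --
and produces the mean-dose vector Z and the between-realization covariance
Var(X|W), together with its sigma2 * K decomposition (tr K = N) and a summary
of how much error is shared between subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseRealizations",
    "DoseUncertaintyModel",
    "SharingSummary",
    "load_realizations",
    "save_realizations",
    "mean_dose",
    "empirical_covariance",
    "covariance_from_cv_correlation",
    "decompose_sigma_k",
    "sharing_summary",
    "load_dose_file",
    "load_correlation_triplets",
    "load_group_file",
]


class DoseFormatError(ValueError):
    """Raised for malformed dose/realization input files."""


@dataclass
class DoseRealizations:
    """N x L matrix of realized doses with subject identifiers.

    Row order of ``values`` defines the alignment of every downstream vector
    and matrix; ``subject_ids`` must be unique.
    """

    subject_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.subject_ids.shape[0]:
            raise DoseFormatError(
                f"{self.subject_ids.shape[0]} subject ids but "
                f"{self.values.shape[0]} dose rows"
            )
        if self.n_subjects < 1:
            raise DoseFormatError("need at least one subject")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.where(~np.isfinite(self.values).all(axis=1))[0][0])
            raise DoseFormatError(
                f"non-finite dose for subject {self.subject_ids[bad]!r} (row {bad})"
            )
        seen: Counter = Counter(self.subject_ids.tolist())
        dups = [k for k, c in seen.items() if c > 1]
        if dups:
            raise DoseFormatError(f"duplicate subject id {dups[0]!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_realizations(self) -> int:
        return self.values.shape[1]


@dataclass
class DoseUncertaintyModel:
    """Mean dose Z plus the covariance Var(X|W) of true dose given W.

    The covariance is held dense (cohorts at the scale handled here fit in
    memory); optional ``groups`` record the sharing structure, in which case
    all cross-group entries are exactly zero and blockwise streaming
    computation is available via :meth:`iter_blocks`.

    ``sigma2_xw`` and ``K`` give the decomposition Var(X|W) = sigma2_xw * K
    with tr(K) = N, separating the overall error magnitude from the sharing
    pattern.
    """

    subject_ids: np.ndarray
    mean_dose: np.ndarray
    covariance: np.ndarray
    groups: np.ndarray | None = None
    correlation: np.ndarray | None = None
    sigma2_xw: float = field(init=False, default=np.nan)
    K: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.mean_dose = np.asarray(self.mean_dose, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        n = self.mean_dose.shape[0]
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape does not match mean dose length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        _validate_psd(self.covariance)
        tr = float(np.trace(self.covariance))
        if tr > 0:
            self.sigma2_xw, self.K = decompose_sigma_k(self.covariance)

    @property
    def n_subjects(self) -> int:
        return self.mean_dose.shape[0]

    def iter_blocks(self) -> Iterable[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Yield (row_index, col_index, block) covering all nonzero structure.

        With known sharing groups the off-diagonal structure is block diagonal
        and each group is yielded once; without groups a single dense block is
        yielded.  Each block is visited exactly once.
        """
        if self.groups is None:
            idx = np.arange(self.n_subjects)
            yield idx, idx, self.covariance
            return
        for g in _unique_in_order(self.groups):
            idx = np.where(self.groups == g)[0]
            yield idx, idx, self.covariance[np.ix_(idx, idx)]

    def quadratic_form(self, m: np.ndarray) -> np.ndarray:
        """M' Var(X|W) M, computed blockwise when sharing groups are known."""
        m = np.asarray(m, dtype=float)
        if m.shape[0] != self.n_subjects:
            raise ValueError("M row count does not match number of subjects")
        out = np.zeros((m.shape[1], m.shape[1]))
        for ri, ci, block in self.iter_blocks():
            out += m[ri].T @ block @ m[ci]
        return out


@dataclass
class SharingSummary:
    n_subjects: int
    n_with_shared_error: int
    fraction_shared: float  # percentage, 0..100
    block_sizes: list[int]


def _unique_in_order(labels: np.ndarray) -> list:
    seen: dict = {}
    for v in labels.tolist():
        seen.setdefault(v, None)
    return list(seen)


def _validate_psd(v: np.ndarray) -> None:
    """Cholesky with a tiny trace-scaled jitter; failure is an error, never a
    silent repair."""
    n = v.shape[0]
    tr = float(np.trace(v))
    if tr == 0.0 and not v.any():
        return  # exact zero matrix (zero-error limit) is trivially PSD
    jitter = 1e-10 * tr / n
    try:
        np.linalg.cholesky(v + jitter * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive semi-definite") from exc


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_realizations(path: str | Path, delimiter: str = ",") -> DoseRealizations:
    """Read a realization matrix: header ``id,r1,...,rL``, one row per subject.

    Files ending in ``.h5``/``.hdf5`` are read as a hierarchical array
    container with datasets ``subject_ids`` and ``values`` (same logical
    schema, for large N x L matrices).
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            ids = [s.decode() if isinstance(s, bytes) else s for s in f["subject_ids"][:]]
            values = f["values"][:]
        return DoseRealizations(np.asarray(ids, dtype=object), values)

    df = pd.read_csv(
        path, delimiter=delimiter, dtype={0: str}, float_precision="round_trip"
    )
    if df.shape[1] < 2:
        raise DoseFormatError(f"{path}: need an id column plus >=1 realization column")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise DoseFormatError(f"{path}: missing/ragged value in data row {row}")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise DoseFormatError(f"{path}: non-numeric dose value ({exc})") from exc
    return DoseRealizations(ids, values)


def save_realizations(r: DoseRealizations, path: str | Path, delimiter: str = ",") -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(
                "subject_ids", data=np.asarray([str(s) for s in r.subject_ids], dtype="S")
            )
            f.create_dataset("values", data=r.values)
        return
    df = pd.DataFrame(
        r.values, columns=[f"r{j + 1}" for j in range(r.n_realizations)]
    )
    df.insert(0, "id", [str(s) for s in r.subject_ids])
    # shortest round-tripping float repr keeps the text form bit-exact
    df.to_csv(path, sep=delimiter, index=False, float_format=lambda x: repr(float(x)))


def load_dose_file(path: str | Path, delimiter: str = ",") -> tuple[np.ndarray, np.ndarray]:
    """Read ``id,dose`` point-dose file; returns (subject_ids, doses)."""
    df = pd.read_csv(path, delimiter=delimiter, dtype={0: str})
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    if len(set(ids.tolist())) != len(ids):
        raise DoseFormatError(f"{path}: duplicate subject id")
    return ids, df.iloc[:, 1].to_numpy(dtype=float)


def load_correlation_triplets(path: str | Path, delimiter: str = ",") -> list[tuple[str, str, float]]:
    """Read sparse correlation triplets ``id_a,id_b,rho``."""
    df = pd.read_csv(path, delimiter=delimiter, dtype={0: str, 1: str})
    return [
        (str(a), str(b), float(r))
        for a, b, r in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    ]


def load_group_file(path: str | Path, delimiter: str = ",") -> dict[str, str]:
    """Read ``id,group`` sharing-group labels (rho = 1 within group)."""
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def mean_dose(r: DoseRealizations) -> np.ndarray:
    """Z: the per-subject sample mean over realizations."""
    return r.values.mean(axis=1)


def empirical_covariance(
    r: DoseRealizations,
    sharing: Sequence | np.ndarray | None = None,
    unbiased: bool = False,
) -> DoseUncertaintyModel:
    """Between-realization covariance (1/L) sum_r (X^r - Z)(X^r - Z)'.

    The default divisor is L, matching the population-style estimator used
    with dosimetry-system output; ``unbiased=True`` switches to L - 1.  If
    ``sharing`` group labels are given, cross-group entries are forced to
    exactly zero (subjects in different groups share no error by assumption).
    """
    L = r.n_realizations
    if L < 2:
        raise ValueError("need at least 2 realizations to estimate Var(X|W)")
    z = mean_dose(r)
    dev = r.values - z[:, None]
    cov = dev @ dev.T / (L - 1 if unbiased else L)
    groups = None
    if sharing is not None:
        groups = np.asarray(sharing, dtype=object)
        if groups.shape[0] != r.n_subjects:
            raise ValueError("sharing labels length does not match subjects")
        same = groups[:, None] == groups[None, :]
        cov = np.where(same, cov, 0.0)
    return DoseUncertaintyModel(r.subject_ids, z, cov, groups=groups)


def covariance_from_cv_correlation(
    z: np.ndarray,
    cv: float,
    corr: Iterable[tuple[str, str, float]] | None = None,
    subject_ids: Sequence | None = None,
) -> DoseUncertaintyModel:
    """Var(X|W) = C o (cv^2 Z Z') from point doses and sparse correlations.

    ``o`` is element-wise multiplication: Var_ij = rho_ij cv^2 Z_i Z_j with
    unit-diagonal C, so the diagonal is cv^2 Z_i^2 (at 50% CV the variance is
    0.25 times the squared dose estimate).
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if cv < 0:
        raise ValueError("coefficient of variation must be nonnegative")
    if subject_ids is None:
        subject_ids = np.array([str(i) for i in range(n)], dtype=object)
    subject_ids = np.asarray(subject_ids, dtype=object)
    index = {str(s): i for i, s in enumerate(subject_ids)}

    c = np.eye(n)
    if corr is not None:
        triplets = list(corr)
        seen: dict[tuple[int, int], float] = {}
        for a, b, rho in triplets:
            if abs(rho) > 1:
                raise ValueError(f"|rho| > 1 for pair ({a}, {b})")
            ia, ib = index[str(a)], index[str(b)]
            key = (min(ia, ib), max(ia, ib))
            if key in seen and seen[key] != rho:
                raise ValueError(f"asymmetric/conflicting correlation for ({a}, {b})")
            seen[key] = rho
            c[ia, ib] = c[ib, ia] = rho
    cov = c * (cv**2 * np.outer(z, z))
    return DoseUncertaintyModel(subject_ids, z, cov, correlation=c)


def decompose_sigma_k(v: np.ndarray) -> tuple[float, np.ndarray]:
    """Split a covariance into sigma2_xw * K with tr(K) = N exactly."""
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    tr = float(np.trace(v))
    if tr <= 0:
        raise ValueError("degenerate covariance: trace must be positive")
    sigma2 = tr / n
    return sigma2, v / sigma2


def sharing_summary(v: DoseUncertaintyModel, tol: float = 0.0) -> SharingSummary:
    """Count subjects with any off-diagonal |Var_ij| exceeding ``tol``.

    ``tol=0`` means exact nonzero, appropriate for constructions (like
    C o cv^2 ZZ') that produce exact zeros.
    """
    cov = v.covariance.copy()
    np.fill_diagonal(cov, 0.0)
    linked = np.abs(cov) > tol
    shared_mask = linked.any(axis=1)
    n = v.n_subjects
    n_shared = int(shared_mask.sum())
    # connected components of the sharing graph give the block sizes
    block_sizes: list[int] = []
    if n_shared:
        from scipy.sparse.csgraph import connected_components
        from scipy.sparse import csr_matrix

        ncomp, labels = connected_components(csr_matrix(linked), directed=False)
        for k in range(ncomp):
            size = int((labels == k).sum())
            if size > 1:
                block_sizes.append(size)
    return SharingSummary(
        n_subjects=n,
        n_with_shared_error=n_shared,
        fraction_shared=100.0 * n_shared / n,
        block_sizes=sorted(block_sizes),
    )
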