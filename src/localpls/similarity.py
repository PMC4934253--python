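"""Spectral similarity scores and calibration-sample ranking.

The headline score is the synthetic degree of grey relational coefficient
(S-GRC), a convex blend of two grey-relational measures:

* the *absolute degree* ``eps`` compares the magnitudes of the trapezoid-style
  sequence sums ``s = sum(x[0..n-2]) + 0.5 * x[n-1]`` of the two spectra;
* the *relative degree* ``gamma`` compares pointwise deviations of the query
  from a calibration spectrum against the per-wavelength minimum and maximum
  deviation over the whole calibration ensemble, softened by a distinguishing
  coefficient ``xi``.

``rho = theta * eps + (1 - theta) * gamma`` lies in (0, 1]; 1 means identical.
Classical grey relational analysis first shifts each sequence to start at
zero; the blend here works on the raw sequences by default, with the shift
available behind ``GRCParams.zero_start``.

Comparator criteria (Euclidean distance, Mahalanobis distance in PCA-score
space, spectral angle) use their standard definitions; ranking converts every
criterion onto a common "larger = more similar" scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

SIMILARITY_METHODS = ("sgrc", "euclidean", "mahalanobis", "angle")
#: methods whose raw score is a distance (smaller = more similar)
_DISTANCE_METHODS = frozenset({"euclidean", "mahalanobis", "angle"})


@dataclass(frozen=True)
class GRCParams:
    """S-GRC parameters.

    theta : weight on the absolute degree (0.2 puts 0.8 on the relative
        degree, which better separates overlapping spectra).
    xi : distinguishing coefficient of the relative degree (0.5 customary).
    zero_start : apply the classical start-at-zero shift x(k) - x(1) before
        the absolute-degree sums (off by default; the raw-sum form is the
        native definition here).
    """

    theta: float = 0.2
    xi: float = 0.5
    zero_start: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")


@dataclass(frozen=True)
class MahalanobisParams:
    """PCA-score Mahalanobis comparator: number of principal components."""

    n_scores: int = 2

    def __post_init__(self) -> None:
        if self.n_scores < 1:
            raise ValueError("n_scores must be >= 1")


@dataclass
class SimilarityRanking:
    """Ordering of calibration samples for one query, most similar first."""

    query_id: str
    method: str
    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        m = self.order.size
        if sorted(self.order.tolist()) != list(range(m)):
            raise ValueError("order must be a permutation of 0..m-1")
        if self.scores.size != m:
            raise ValueError("scores length must match order")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing along order")
        if self.method not in SIMILARITY_METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def to_frame(self, calibration_ids=None):
        """Scores as a table (query_id, calibration_id, method, score, rank)."""
        import pandas as pd

        ids = (
            [str(i) for i in self.order]
            if calibration_ids is None
            else [calibration_ids[i] for i in self.order]
        )
        return pd.DataFrame(
            {
                "query_id": self.query_id,
                "calibration_id": ids,
                "method": self.method,
                "score": self.scores,
                "rank": np.arange(1, self.order.size + 1),
            }
        )


def _sequence_sum(x: np.ndarray, zero_start: bool) -> np.ndarray:
    """s = sum of all but the last entry plus half the last entry, row-wise."""
    x = np.atleast_2d(x)
    if zero_start:
        x = x - x[:, :1]
    return x[:, :-1].sum(axis=1) + 0.5 * x[:, -1]


def absolute_grc(xi: np.ndarray, xj: np.ndarray, zero_start: bool = False) -> float:
    """Absolute degree of grey relation between two equal-length spectra.

    eps = (1 + |s_i| + |s_j|) / (1 + |s_i| + |s_j| + |s_i - s_j|), symmetric,
    in (0, 1]; equals 1 iff the sequence sums coincide.
    """
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if xi.size != xj.size:
        raise ValueError("spectra must have equal length")
    if xi.size < 2:
        raise ValueError("spectra must have length >= 2")
    si = abs(_sequence_sum(xi, zero_start)[0])
    sj = abs(_sequence_sum(xj, zero_start)[0])
    sij = abs(_sequence_sum((xi - xj)[None, :], zero_start)[0])
    return (1.0 + si + sj) / (1.0 + si + sj + sij)


def _relative_grc_all(query: np.ndarray, cal: np.ndarray, xi_coef: float) -> np.ndarray:
    """Relative degree of every calibration row against the query.

    Per wavelength k the deviations Delta_l(k) = |cal[l, k] - query[k]| are
    reduced to their min and max over the ensemble; row j scores
    gamma_j = mean_k (min + xi*max) / (Delta_j + xi*max), with 0/0 -> 1
    (the limit when every deviation vanishes at a wavelength).
    """
    delta = np.abs(cal - query[None, :])  # (m_c, n)
    dmin = delta.min(axis=0)
    dmax = delta.max(axis=0)
    num = dmin + xi_coef * dmax  # (n,)
    den = delta + xi_coef * dmax[None, :]  # (m_c, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0.0, num[None, :] / np.where(den > 0.0, den, 1.0), 1.0)
    return ratio.mean(axis=1)


def relative_grc(query: np.ndarray, j: int, cal: np.ndarray, xi_coef: float = 0.5) -> float:
    """Relative degree of grey relation of calibration row ``j`` vs the query."""
    query = np.asarray(query, dtype=float).ravel()
    cal = np.atleast_2d(np.asarray(cal, dtype=float))
    if cal.shape[0] < 1:
        raise ValueError("calibration set must be non-empty")
    if cal.shape[1] != query.size:
        raise ValueError("query length must match calibration columns")
    return float(_relative_grc_all(query, cal, xi_coef)[j])


def sgrc_scores(query: np.ndarray, cal: np.ndarray, params: GRCParams | None = None) -> np.ndarray:
    """S-GRC of the query against every calibration row (vector, length m_c)."""
    if params is None:
        params = GRCParams()
    query = np.asarray(query, dtype=float).ravel()
    cal = np.atleast_2d(np.asarray(cal, dtype=float))
    if cal.shape[0] < 1:
        raise ValueError("calibration set must be non-empty")
    if cal.shape[1] != query.size:
        raise ValueError("query length must match calibration columns")
    if query.size < 2:
        raise ValueError("spectra must have length >= 2")
    s_cal = _sequence_sum(cal, params.zero_start)
    s_q = _sequence_sum(query[None, :], params.zero_start)[0]
    s_diff = _sequence_sum(cal - query[None, :], params.zero_start)
    si, sj, sij = abs(s_q), np.abs(s_cal), np.abs(s_diff)
    eps = (1.0 + si + sj) / (1.0 + si + sj + sij)
    gamma = _relative_grc_all(query, cal, params.xi)
    return params.theta * eps + (1.0 - params.theta) * gamma


def euclidean_scores(query: np.ndarray, cal: np.ndarray) -> np.ndarray:
    """L2 distance of the query to every calibration spectrum."""
    query = np.asarray(query, dtype=float).ravel()
    cal = np.atleast_2d(np.asarray(cal, dtype=float))
    return np.linalg.norm(cal - query[None, :], axis=1)


def angle_scores(query: np.ndarray, cal: np.ndarray) -> np.ndarray:
    """Spectral angle (radians) between the query and every calibration row."""
    query = np.asarray(query, dtype=float).ravel()
    cal = np.atleast_2d(np.asarray(cal, dtype=float))
    qn = np.linalg.norm(query)
    cn = np.linalg.norm(cal, axis=1)
    if qn == 0.0 or np.any(cn == 0.0):
        raise ValueError("spectral angle undefined for a zero-norm spectrum")
    cosang = (cal @ query) / (cn * qn)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def mahalanobis_scores(
    query: np.ndarray, cal: np.ndarray, params: MahalanobisParams | None = None
) -> np.ndarray:
    """Mahalanobis distance in PCA-score space.

    Spectra are mean-centered on the calibration set and projected onto its
    top ``n_scores`` principal components; the distance of each calibration
    score row to the query score uses the inverse covariance of the
    calibration scores.  A tiny ridge is added if that covariance is singular.
    """
    if params is None:
        params = MahalanobisParams()
    query = np.asarray(query, dtype=float).ravel()
    cal = np.atleast_2d(np.asarray(cal, dtype=float))
    m_c, n = cal.shape
    k = params.n_scores
    if k > min(m_c - 1, n):
        raise ValueError(f"n_scores={k} needs m_c > n_scores and n >= n_scores")
    mean = cal.mean(axis=0)
    Xc = cal - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:k]
    # deterministic sign: largest-magnitude loading positive
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    T = Xc @ comps.T  # (m_c, k)
    t_q = (query - mean) @ comps.T
    cov = np.atleast_2d(np.cov(T, rowvar=False))
    if not np.isfinite(np.linalg.cond(cov)) or np.linalg.cond(cov) > 1e12:
        warnings.warn("singular score covariance; adding ridge", RuntimeWarning)
        cov = cov + (1e-10 * np.trace(cov) / k + 1e-30) * np.eye(k)
    diff = T - t_q[None, :]
    md2 = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
    return np.sqrt(np.maximum(md2, 0.0))


def rank_calibration(scores: np.ndarray, method: str, query_id: str = "") -> SimilarityRanking:
    """Sort calibration samples onto a common "larger = more similar" scale.

    Similarity scores (sgrc) sort descending; distance scores sort ascending
    and are negated.  Ties break toward the lower calibration index.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if np.any(np.isnan(scores)):
        raise ValueError("NaN similarity score")
    common = -scores if method in _DISTANCE_METHODS else scores
    # primary key: descending score; secondary: ascending index
    order = np.lexsort((np.arange(common.size), -common))
    return SimilarityRanking(
        query_id=query_id, method=method, order=order, scores=common[order]
    )


def score_query(
    query: np.ndarray,
    cal: np.ndarray,
    method: str = "sgrc",
    grc: GRCParams | None = None,
    mahalanobis: MahalanobisParams | None = None,
) -> np.ndarray:
    """Dispatch raw scores for one query under the named criterion."""
    if method == "sgrc":
        return sgrc_scores(query, cal, grc)
    if method == "euclidean":
        return euclidean_scores(query, cal)
    if method == "angle":
        return angle_scores(query, cal)
    if method == "mahalanobis":
        return mahalanobis_scores(query, cal, mahalanobis)
    raise ValueError(f"unknown method {method!r}")
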