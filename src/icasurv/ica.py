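"""Spatial ICA: MDL model-order estimation, PCA whitening and Infomax.

The data model is ``X = A S``: a subjects-by-voxels matrix ``X`` decomposed
into mixing coefficients ``A`` (subjects x components) and spatial sources
``S`` (components x voxels).  Voxels are treated as the sample dimension.

Normalisation conventions (applied by :func:`normalize_decomposition`):
each source row has unit (population) variance, and the source value of
largest magnitude is positive; mixing columns absorb the inverse scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import SubjectMatrix

__all__ = [
    "Decomposition",
    "estimate_order_mdl",
    "whiten",
    "infomax_update",
    "infomax_ica",
    "decompose",
    "normalize_decomposition",
    "match_components",
]


@dataclass
class Decomposition:
    """Result of a spatial ICA run."""

    mixing: np.ndarray        # subjects x components
    sources: np.ndarray       # components x voxels
    order: int
    row_means: np.ndarray     # per-subject mean removed before whitening
    n_iter: int = 0
    final_update: float = 0.0
    converged: bool = True
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Rank-``order`` reconstruction of the (row-centered) data."""
        return self.mixing @ self.sources


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SubjectMatrix):
        return data.data
    return np.asarray(data, dtype=np.float64)


def estimate_order_mdl(data, n_max: int | None = None) -> int:
    """Model order by the eigenvalue-based minimum-description-length rule.

    For ``p`` subjects observed over ``N`` voxels, with sorted covariance
    eigenvalues ``l_1 >= ... >= l_p``, the criterion at order ``k`` is::

        MDL(k) = -N (p-k) log(gm_k / am_k) + 0.5 k (2p - k + 1) log N

    where ``gm_k`` / ``am_k`` are the geometric / arithmetic means of the
    smallest ``p-k`` eigenvalues.  Returns the minimising ``k`` in
    ``[0, p-1]``.  The voxel count is taken as the effective number of
    i.i.d. samples, which is optimistic under spatial smoothing; pass
    ``n_max`` to cap the search range.
    """
    x = _as_matrix(data)
    p, n_vox = x.shape
    if p < 3:
        raise ValueError("need at least 3 subjects for order estimation")
    if n_vox < p + 1:
        raise ValueError("need more voxels than subjects")
    if np.allclose(x, x[0], atol=0, rtol=1e-12):
        raise ValueError("degenerate covariance: all subject rows are equal")
    xc = x - x.mean(axis=1, keepdims=True)
    cov = (xc @ xc.T) / n_vox
    eig = np.linalg.eigvalsh(cov)[::-1]
    if eig[0] <= 0 or not np.isfinite(eig).all():
        raise ValueError("degenerate covariance (zero variance?)")
    eig = np.clip(eig, eig[0] * 1e-15, None)

    k_hi = p - 1 if n_max is None else min(n_max, p - 1)
    log_n = np.log(n_vox)
    log_eig = np.log(eig)
    # suffix sums for arithmetic/geometric means of the trailing eigenvalues
    suf_sum = np.cumsum(eig[::-1])[::-1]
    suf_logsum = np.cumsum(log_eig[::-1])[::-1]
    mdl = np.empty(k_hi + 1)
    for k in range(k_hi + 1):
        m = p - k
        log_gm = suf_logsum[k] / m
        log_am = np.log(suf_sum[k] / m)
        mdl[k] = -n_vox * m * (log_gm - log_am) + 0.5 * k * (2 * p - k + 1) * log_n
    return int(np.argmin(mdl))


def whiten(data, order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten the row-centered data down to ``order`` components.

    Returns ``(y, dewhitening, row_means)`` where ``y`` (order x voxels) has
    identity covariance and ``dewhitening @ y`` is the rank-``order``
    projection of the centered data.
    """
    x = _as_matrix(data)
    p, n_vox = x.shape
    if not 1 <= order <= p - 1:
        raise ValueError(f"order must be in [1, {p - 1}], got {order}")
    row_means = x.mean(axis=1, keepdims=True)
    xc = x - row_means
    cov = (xc @ xc.T) / n_vox
    eigval, eigvec = np.linalg.eigh(cov)
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    rank = int(np.sum(eigval > max(eigval[0], 0) * 1e-10))
    if order > rank:
        raise ValueError(
            f"requested order {order} exceeds numerical rank {rank}"
        )
    d = np.sqrt(eigval[:order])
    y = (eigvec[:, :order] / d).T @ xc
    dewhitening = eigvec[:, :order] * d
    return y, dewhitening, row_means[:, 0]


def infomax_update(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One unit-rate natural-gradient Infomax step (logistic nonlinearity).

    ``(I + (1 - 2 g(U)) U^T / N) W`` with ``U = W Y``; zero in expectation
    exactly when the unmixed rows are independent with the standard logistic
    density (the algorithm's fixed point).
    """
    u = w @ y
    g = 1.0 / (1.0 + np.exp(-u))
    return (np.eye(w.shape[0]) + (1.0 - 2.0 * g) @ u.T / y.shape[1]) @ w


def infomax_ica(
    data,
    order: int | None = None,
    learning_rate: float = 0.05,
    anneal_deg: float = 60.0,
    anneal_factor: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 512,
    seed: int = 0,
    w_init: np.ndarray | None = None,
) -> Decomposition:
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    The whitened data are unmixed by full-batch natural-gradient ascent on
    the Infomax objective, ``dW = lr (I + (1 - 2 g(U)) U^T / N) W`` with
    ``g`` the logistic sigmoid and ``U = W Y``.  The learning rate is halved
    whenever the angle between successive updates exceeds ``anneal_deg``
    degrees.  Iteration stops when the relative update norm drops below
    ``tol`` or after ``max_iter`` sweeps; non-convergence is flagged and
    warned about but a result is still returned.

    Deterministic for a fixed ``seed`` (random orthogonal initialisation,
    unless an explicit ``w_init`` unmixing matrix is supplied).
    """
    x = _as_matrix(data)
    if order is None:
        order = estimate_order_mdl(x)
        if order < 1:
            raise ValueError("MDL estimated order 0; supply an explicit order")
    y, dewhite, row_means = whiten(x, order)
    k, n_vox = y.shape

    if w_init is not None:
        w = np.array(w_init, dtype=float)
        if w.shape != (k, k):
            raise ValueError(f"w_init must be {k}x{k}")
    else:
        rng = np.random.default_rng(seed)
        w, _ = np.linalg.qr(rng.standard_normal((k, k)))
    lr = learning_rate
    prev_delta = None
    update = np.inf
    for it in range(1, max_iter + 1):
        delta = lr * infomax_update(w, y)
        if prev_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
            if denom > 0:
                cosang = float(np.sum(delta * prev_delta) / denom)
                if cosang < np.cos(np.deg2rad(anneal_deg)):
                    lr *= anneal_factor
                    delta = anneal_factor * delta
        w = w + delta
        update = np.linalg.norm(delta) / max(np.linalg.norm(w), 1e-300)
        prev_delta = delta
        if update < tol:
            break
    converged = update < tol
    if not converged:
        warnings.warn(
            f"Infomax did not converge in {max_iter} iterations "
            f"(final relative update {update:.2e})",
            RuntimeWarning,
        )
    sources = w @ y
    mixing = dewhite @ np.linalg.inv(w)
    dec = Decomposition(
        mixing=mixing,
        sources=sources,
        order=order,
        row_means=row_means,
        n_iter=it,
        final_update=float(update),
        converged=converged,
        seed=seed,
    )
    return normalize_decomposition(dec)


def normalize_decomposition(dec: Decomposition) -> Decomposition:
    """Apply the unit-variance / positive-peak convention (idempotent).

    Source rows are scaled to unit population variance and flipped so the
    value of largest magnitude is positive; mixing columns are rescaled so
    ``mixing @ sources`` is unchanged.
    """
    sources = dec.sources.copy()
    mixing = dec.mixing.copy()
    sd = sources.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("cannot normalize a constant source row")
    sources /= sd[:, None]
    mixing *= sd[None, :]
    peaks = sources[np.arange(sources.shape[0]), np.argmax(np.abs(sources), axis=1)]
    flip = np.where(peaks < 0, -1.0, 1.0)
    sources *= flip[:, None]
    mixing *= flip[None, :]
    return Decomposition(
        mixing=mixing,
        sources=sources,
        order=dec.order,
        row_means=dec.row_means,
        n_iter=dec.n_iter,
        final_update=dec.final_update,
        converged=dec.converged,
        seed=dec.seed,
    )


def decompose(
    data,
    order: int | None = None,
    seed: int = 0,
    **infomax_kwargs,
) -> Decomposition:
    """Convenience wrapper: MDL order (unless given) then Infomax."""
    if order is None:
        order = estimate_order_mdl(_as_matrix(data))
    return infomax_ica(data, order=order, seed=seed, **infomax_kwargs)


def match_components(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy best |correlation| matching of estimated to reference rows.

    Returns ``(perm, corrs)`` where ``estimated[perm[i]]`` matches
    ``reference[i]`` with absolute Pearson correlation ``corrs[i]``.
    Used to resolve ICA's permutation/sign ambiguity in recovery checks.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    est_c = est - est.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=1, keepdims=True)
    est_c /= np.linalg.norm(est_c, axis=1, keepdims=True)
    ref_c /= np.linalg.norm(ref_c, axis=1, keepdims=True)
    corr = np.abs(ref_c @ est_c.T)  # ref x est
    perm = np.full(ref.shape[0], -1)
    corrs = np.zeros(ref.shape[0])
    avail = set(range(est.shape[0]))
    # assign best pairs first (greedy Hungarian stand-in; fine for |corr|~1)
    order_pairs = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
    done: set[int] = set()
    for i, j in order_pairs:
        if i in done or j not in avail:
            continue
        perm[i], corrs[i] = j, corr[i, j]
        done.add(int(i))
        avail.discard(int(j))
        if len(done) == ref.shape[0]:
            break
    return perm, corrs
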