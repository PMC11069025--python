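"""Group spatial ICA: PCA reduction, MDL order selection, infomax unmixing,
ICASSO stability selection, and GICA3 back-reconstruction.

The group model treats each subject's centered data X_i (frames x voxels) as a
mixture of C spatially independent maps shared across subjects.  Reduction is
two-stage: a temporal PCA per subject to l1 dimensions, concatenation over
subjects, then a group PCA to C whitened dimensions on which infomax runs.
Stability is assessed ICASSO-style by re-running infomax from random starts,
clustering the pooled estimates by absolute spatial correlation, and keeping
cluster centrotypes with a quality index Iq.  Subject maps and timecourses are
recovered with GICA3, whose defining property — the mean over subjects of the
back-reconstructed maps equals the aggregate map — is exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------------
# model order (MDL, Wax-Kailath form)
# ---------------------------------------------------------------------------

def estimate_order_mdl(data_matrix: np.ndarray, n_samples_effective: int | None = None) -> int:
    """Minimum-description-length estimate of the number of components.

    ``data_matrix`` is frames x voxels; eigenvalues are those of the temporal
    covariance with voxels as samples.  MDL(k) = -N(p-k) log(g_k/a_k)
    + k(2p-k+1)/2 * log N, with g_k/a_k the geometric/arithmetic means of the
    trailing eigenvalues.  ``n_samples_effective`` defaults to the voxel count
    and stands in for any i.i.d.-sample correction.  Returns at least 1.
    """
    x = np.asarray(data_matrix, dtype=float)
    p, n_vox = x.shape
    n = int(n_samples_effective) if n_samples_effective else n_vox
    xc = x - x.mean(axis=1, keepdims=True)
    lam = np.linalg.eigvalsh(xc @ xc.T / n_vox)[::-1]
    floor = lam[0] * 1e-12 if lam[0] > 0 else 0.0
    good = lam > floor
    if not good.all():
        warnings.warn(
            f"covariance spectrum truncated from {p} to {int(good.sum())} eigenvalues"
        )
        lam = lam[good]
        p = len(lam)
    mdl = np.empty(p - 1)
    for k in range(p - 1):
        tail = lam[k:]
        g = np.exp(np.mean(np.log(tail)))
        a = np.mean(tail)
        mdl[k] = -n * (p - k) * np.log(g / a) + 0.5 * k * (2 * p - k + 1) * np.log(n)
    return max(int(np.argmin(mdl)), 1)


# ---------------------------------------------------------------------------
# two-stage PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class Reduction:
    """Projection matrices retained from the two-stage PCA.

    For subject i with centered data X_i (T x V): X_i ≈ F_i Y_i with F_i the
    top-l1 left singular vectors and Y_i = F_i^T X_i.  Stacking Y_i row-wise
    gives Y; group PCA yields G (M*l1 x c, orthonormal columns) and voxel-wise
    eigenvalues D so that the whitened matrix Z_w = D^{-1/2} G^T Y has identity
    spatial covariance.
    """

    subject_bases: list[np.ndarray]  # F_i, T_i x l1
    subject_reduced: list[np.ndarray]  # Y_i, l1 x V
    subject_means: list[np.ndarray]  # voxelwise temporal means, V
    group_basis: np.ndarray  # G, (M*l1) x c
    group_eigvals: np.ndarray  # D diagonal, c
    whitened: np.ndarray  # Z_w, c x V
    l1: int
    c: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_bases)

    def subject_partition(self, i: int) -> np.ndarray:
        """G_i: subject i's l1 x c block of the group PCA basis."""
        return self.group_basis[i * self.l1 : (i + 1) * self.l1]


def two_stage_pca(subject_matrices: list[np.ndarray], l1: int, c: int) -> Reduction:
    """Subject-level then group-level PCA with whitening.

    Each subject matrix is frames x voxels; voxelwise temporal means are
    removed before the subject PCA.
    """
    if l1 < c:
        raise ValueError(f"subject PCA dimension l1={l1} must be >= group order c={c}")
    bases, reduced, means = [], [], []
    for i, x in enumerate(subject_matrices):
        x = np.asarray(x, dtype=float)
        if x.shape[0] < l1:
            raise ValueError(f"subject {i}: l1={l1} exceeds frame count {x.shape[0]}")
        mu = x.mean(axis=0)
        xc = x - mu
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        bases.append(u[:, :l1])
        reduced.append(u[:, :l1].T @ xc)
        means.append(mu)
    y = np.vstack(reduced)
    n_vox = y.shape[1]
    ug, sg, _ = np.linalg.svd(y, full_matrices=False)
    g = ug[:, :c]
    d = sg[:c] ** 2 / n_vox
    if np.any(d <= 0):
        raise ValueError("group covariance is rank deficient below the requested order")
    z_w = (g.T @ y) / np.sqrt(d)[:, None]
    return Reduction(
        subject_bases=bases,
        subject_reduced=reduced,
        subject_means=means,
        group_basis=g,
        group_eigvals=d,
        whitened=z_w,
        l1=l1,
        c=c,
    )


# ---------------------------------------------------------------------------
# infomax ICA
# ---------------------------------------------------------------------------

def infomax_ica(
    whitened: np.ndarray,
    c: int | None = None,
    seed: int = 0,
    learning_rate: float = 0.01,
    max_steps: int = 4096,
    tol: float = 1e-6,
    anneal: float = 0.97,
) -> tuple[np.ndarray, np.ndarray]:
    """Natural-gradient infomax with logistic nonlinearity.

    Returns the square unmixing matrix W and spatial sources S = W @ whitened.
    The learning rate anneals whenever the gradient direction swings by more
    than 60 degrees; iteration stops when the applied weight-change norm drops
    below ``tol`` or at ``max_steps``.  Deterministic for a fixed seed; on
    divergence the fit restarts at half the rate (up to 3 restarts).
    """
    z = np.asarray(whitened, dtype=float)
    if c is None:
        c = z.shape[0]
    if z.shape[0] != c:
        raise ValueError("whitened data must have one row per component")
    n = z.shape[1]
    rng = np.random.default_rng(seed)
    w0, _ = np.linalg.qr(rng.standard_normal((c, c)))
    eye = np.identity(c)

    for attempt in range(4):
        w = w0.copy()
        lr = learning_rate / (2**attempt)
        prev_dw = None
        diverged = False
        for _ in range(max_steps):
            u = w @ z
            y = 1.0 / (1.0 + np.exp(-u))
            dw = lr * (eye + (1.0 - 2.0 * y) @ u.T / n) @ w
            if not np.isfinite(dw).all() or np.abs(w + dw).max() > 1e8:
                diverged = True
                break
            if prev_dw is not None:
                cosang = (dw * prev_dw).sum() / (
                    np.linalg.norm(dw) * np.linalg.norm(prev_dw) + 1e-30
                )
                if cosang < 0.5:  # > 60 degree swing
                    lr *= anneal
            w = w + dw
            prev_dw = dw
            if np.linalg.norm(dw) < tol:
                break
        if not diverged:
            return w, w @ z
    raise RuntimeError("infomax diverged after 3 restarts at reduced learning rates")


# ---------------------------------------------------------------------------
# ICASSO stability selection
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """Aggregate result of group ICA with stability indices.

    aggregate_maps are z-scored over the mask (zero mean, unit SD, extreme
    voxel positive); unmixing/mixing act on the whitened group data.
    """

    order: int
    aggregate_maps: np.ndarray  # C x V, z-scored
    group_timecourses: np.ndarray  # (sum_i T_i) x C
    stability_iq: np.ndarray  # C
    unmixing: np.ndarray  # C x C on whitened data
    mixing: np.ndarray  # C x C, pinv(unmixing)
    reduction: Reduction
    mask_scale: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)  # type: ignore


@dataclass
class SubjectComponents:
    maps: np.ndarray  # subjects x C x V
    timecourses: list[np.ndarray]  # per subject, T_i x C


def zscore_maps(maps: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score each map over mask voxels; flip sign so the extreme voxel is positive.

    ``maps`` is C x V (V = mask voxels when mask is None or already applied).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    out = np.empty_like(maps)
    for i, m in enumerate(maps):
        v = m if mask is None else m[np.asarray(mask, bool).ravel()]
        sd = v.std()
        if sd == 0:
            raise ValueError(f"map {i} has zero variance over the mask")
        z = (m - v.mean()) / sd
        if z[np.abs(z).argmax()] < 0:
            z = -z
        out[i] = z
    return out


def _centrotype_clusters(sources: np.ndarray, c: int):
    """Average-linkage clustering of pooled ICA estimates on 1 - |corr|."""
    sim = np.abs(np.corrcoef(sources))
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    labels = fcluster(linkage(dist, method="average"), t=c, criterion="maxclust")
    return sim, labels


def icasso(
    whitened: np.ndarray,
    c: int,
    n_runs: int = 10,
    base_seed: int = 0,
    **infomax_kwargs,
):
    """Run infomax ``n_runs`` times, cluster estimates, return centrotypes + Iq.

    Returns (centrotype sources C x V, unmixing rows W_c, iq array).  Iq per
    cluster = mean within-cluster |corr| - mean between-cluster |corr|; for a
    single run (or identical seeds) every Iq is 1 by construction.
    """
    if n_runs < 2:
        raise ValueError("ICASSO needs at least 2 runs")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs) % (2**31)
    all_w, all_s = [], []
    for s in seeds:
        w, src = infomax_ica(whitened, seed=int(s), **infomax_kwargs)
        all_w.append(w)
        all_s.append(src)
    pooled = np.vstack(all_s)  # (n_runs*c) x V
    w_rows = np.vstack(all_w)
    sim, labels = _centrotype_clusters(pooled, c)
    cluster_ids = np.unique(labels)
    if len(cluster_ids) < c:
        warnings.warn(f"only {len(cluster_ids)} estimate clusters found for order {c}")
    centro_idx, iqs = [], []
    for cid in cluster_ids:
        inside = np.flatnonzero(labels == cid)
        outside = np.flatnonzero(labels != cid)
        sub = sim[np.ix_(inside, inside)]
        if len(inside) > 1:
            within = (sub.sum(axis=1) - 1.0) / (len(inside) - 1)
            mean_within = within.mean()
        else:
            within = np.array([1.0])
            mean_within = 1.0
        between = sim[np.ix_(inside, outside)].mean() if outside.size else 0.0
        iqs.append(mean_within - between)
        centro_idx.append(inside[np.argmax(sim[np.ix_(inside, inside)].sum(axis=1))])
    order = np.argsort(iqs)[::-1]
    centro_idx = [centro_idx[i] for i in order]
    iqs = np.asarray([iqs[i] for i in order])
    return pooled[centro_idx], w_rows[centro_idx], iqs


def run_group_ica(
    subject_matrices: list[np.ndarray],
    c: int,
    l1: int | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    **infomax_kwargs,
) -> ComponentSet:
    """Full group ICA: reduction, ICASSO-stabilised infomax, aggregate maps.

    ``l1`` defaults to round(1.5 * c).  The centrotype unmixing is refined so
    that W is the exact least-squares unmixing of the whitened data onto the
    centrotype sources, keeping S = W Z_w an identity.
    """
    if l1 is None:
        l1 = int(round(1.5 * c))
    red = two_stage_pca(subject_matrices, l1=l1, c=c)
    sources, w, iq = icasso(red.whitened, c=c, n_runs=n_runs, base_seed=base_seed, **infomax_kwargs)
    # orient and scale: flip so the extreme voxel is positive, normalise each
    # source row to unit voxel variance so the z-scored map and its timecourse
    # stay a consistent factorisation of the data (amplitude lives in the TC)
    scale = np.ones(len(sources))
    for i, s in enumerate(sources):
        sd = s.std()
        scale[i] = 1.0 / sd if sd > 0 else 1.0
        if s[np.abs(s).argmax()] < 0:
            scale[i] = -scale[i]
    w = w * scale[:, None]
    sources = sources * scale[:, None]
    mixing = np.linalg.pinv(w)
    agg = zscore_maps(sources)
    # group timecourses: de-whitened partitions stacked over subjects
    tcs = []
    for i in range(red.n_subjects):
        gi = red.subject_partition(i)
        tcs.append(red.subject_bases[i] @ gi @ np.diag(np.sqrt(red.group_eigvals)) @ mixing)
    return ComponentSet(
        order=c,
        aggregate_maps=agg,
        group_timecourses=np.vstack(tcs),
        stability_iq=iq,
        unmixing=w,
        mixing=mixing,
        reduction=red,
    )


# ---------------------------------------------------------------------------
# GICA3 back-reconstruction
# ---------------------------------------------------------------------------

def gica3_backreconstruct(cs: ComponentSet) -> SubjectComponents:
    """Subject maps and timecourses via the GICA3 partitioned projection.

    Timecourses: TC_i = F_i G_i D^{1/2} A.  Maps: S_i = M W D^{-1/2} G_i^T Y_i
    (M = number of subjects), whose mean over subjects equals the aggregate
    source matrix exactly; subject maps are then z-scored with the same
    convention as the aggregate maps are.
    """
    red = cs.reduction
    if red is None:
        raise ValueError("component set carries no reduction info")
    m = red.n_subjects
    d_sqrt = np.sqrt(red.group_eigvals)
    maps = np.empty((m, cs.order, red.whitened.shape[1]))
    tcs = []
    for i in range(m):
        gi = red.subject_partition(i)
        yi = red.subject_reduced[i]
        maps[i] = m * cs.unmixing @ ((gi.T @ yi) / d_sqrt[:, None])
        tcs.append(red.subject_bases[i] @ gi @ (cs.mixing * d_sqrt[:, None]))
    return SubjectComponents(maps=maps, timecourses=tcs)
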