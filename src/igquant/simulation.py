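"""Monte Carlo null models for particle redistribution.

Two null models are provided for association/dissociation inference:

random simulation
    Removes all particles of one size class from the image and
    redistributes the same number uniformly over the region of interest,
    with the constraint that no simulated particle may lie within the
    hard-core distance (default 10 nm, centre-to-centre) of any other
    particle — fixed real particles of the other class or previously
    placed simulated ones.

fitted simulation
    Starts from a random simulation and additionally constrains the
    distribution of pairwise distances between simulated particles to be
    statistically indistinguishable from the real pattern's: a particle
    is picked at random and moved to a fresh uniform hard-core-respecting
    location; the move is kept iff the two-sample Kolmogorov-Smirnov
    p-value between all real-real and all sim-sim pairwise distances does
    not decrease, and the process repeats until p >= 0.1.

Both are pure functions of (inputs, seed): rerunning with the same seed
reproduces coordinates exactly.
"""

from __future__ import annotations

import numpy as np
import shapely
from numba import njit
from scipy.special import kolmogi, kolmogorov
from shapely.geometry import Polygon

from .core_model import ImageRecord, Particle, ProfileROI, particles_xy
from .spatial_stats import InsufficientParticlesError, nnd_from_xy

__all__ = [
    "PackingInfeasibleError",
    "FittedNonConvergenceError",
    "random_simulation",
    "fitted_simulation",
    "simulate_ensemble",
    "ks_two_sample",
]


class PackingInfeasibleError(RuntimeError):
    """Hard-core placement failed within the proposal budget."""


class FittedNonConvergenceError(RuntimeError):
    """Fitted simulation did not reach KS p >= ks_alpha within the cap."""

    def __init__(self, message: str, best_p: float):
        super().__init__(message)
        self.best_p = best_p


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D = sup |F_a - F_b| over the pooled sample;
    p = K(sqrt(mn/(m+n)) * D) with K the Kolmogorov survival function.
    The distance sets compared here are pairwise-distance multisets, not
    i.i.d. samples; the asymptotic p is used as a similarity score, which
    is how the procedure is defined.
    """
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    d = _ks_stat_sorted(a, b)
    en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
    return d, float(kolmogorov(en * d))


def _ks_stat_sorted(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    pooled = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, pooled, side="right") / len(a_sorted)
    cdf_b = np.searchsorted(b_sorted, pooled, side="right") / len(b_sorted)
    return float(np.abs(cdf_a - cdf_b).max())


# ---------------------------------------------------------------------------
# uniform hard-core sampling


class _RoiSampler:
    """Uniform point proposals over a polygon via bounding-box rejection.

    Every location inside the region of interest has equal probability;
    probability is zero outside.  Proposals are drawn in batches for speed.
    """

    def __init__(self, polygon: Polygon):
        self.polygon = polygon
        shapely.prepare(polygon)  # in-place spatial index for intersects_xy
        self.minx, self.miny, self.maxx, self.maxy = polygon.bounds
        self._buffer: np.ndarray = np.empty((0, 2))
        self._pos = 0

    def draw(self, rng: np.random.Generator, batch: int = 256) -> np.ndarray:
        """One uniform in-polygon point (consumes buffered proposals)."""
        while self._pos >= len(self._buffer):
            xs = rng.uniform(self.minx, self.maxx, batch)
            ys = rng.uniform(self.miny, self.maxy, batch)
            inside = shapely.intersects_xy(self.polygon, xs, ys)
            self._buffer = np.column_stack([xs[inside], ys[inside]])
            self._pos = 0
        pt = self._buffer[self._pos]
        self._pos += 1
        return pt


def _place_hard_core(
    n: int,
    sampler: _RoiSampler,
    fixed_xy: np.ndarray,
    hard_core_nm: float,
    rng: np.random.Generator,
    max_attempts: int,
) -> np.ndarray:
    """Place n points uniformly in the ROI, all >= hard_core_nm from every
    fixed point and from each other.  Sequential rejection sampling."""
    hc2 = hard_core_nm * hard_core_nm
    placed = np.empty((n, 2))
    n_placed = 0
    attempts = 0
    while n_placed < n:
        if attempts >= max_attempts:
            raise PackingInfeasibleError(
                f"placed {n_placed}/{n} particles after {attempts} proposals "
                f"(hard core {hard_core_nm} nm)"
            )
        pt = sampler.draw(rng)
        attempts += 1
        if len(fixed_xy) and (((fixed_xy - pt) ** 2).sum(axis=1) < hc2).any():
            continue
        if n_placed and (((placed[:n_placed] - pt) ** 2).sum(axis=1) < hc2).any():
            continue
        placed[n_placed] = pt
        n_placed += 1
    return placed


def random_simulation(
    n: int,
    roi: ProfileROI | Polygon,
    fixed_xy: np.ndarray | None = None,
    hard_core_nm: float = 10.0,
    seed: int = 0,
    max_attempts: int = 1_000_000,
    _sampler: _RoiSampler | None = None,
) -> np.ndarray:
    """Redistribute ``n`` particles uniformly over the ROI with a hard core.

    Returns an (n, 2) array of simulated centres.  ``fixed_xy`` holds the
    particles that stay in place (the other size class); real particles of
    the simulated class are removed first and do not constrain placement.
    Deterministic given ``seed``.
    """
    polygon = roi.shapely_polygon() if isinstance(roi, ProfileROI) else roi
    sampler = _sampler if _sampler is not None else _RoiSampler(polygon)
    fixed = np.empty((0, 2)) if fixed_xy is None else np.asarray(fixed_xy, float)
    rng = np.random.default_rng(seed)
    return _place_hard_core(n, sampler, fixed, hard_core_nm, rng, max_attempts)


# ---------------------------------------------------------------------------
# fitted simulation


@njit(cache=False)
def _ks_stat_merge(a_sorted, b_sorted):  # pragma: no cover - exercised via tests
    """sup |F_a - F_b| by a two-pointer merge of two sorted arrays."""
    m, n = len(a_sorted), len(b_sorted)
    i = j = 0
    d = 0.0
    while i < m and j < n:
        x = a_sorted[i] if a_sorted[i] <= b_sorted[j] else b_sorted[j]
        while i < m and a_sorted[i] == x:
            i += 1
        while j < n and b_sorted[j] == x:
            j += 1
        diff = abs(i / m - j / n)
        if diff > d:
            d = diff
    return d


@njit(cache=False)
def _replace_sorted(cur_sorted, rem_sorted, add_sorted, out):  # pragma: no cover
    """out = cur_sorted with one instance of each rem value replaced by add.

    All arrays sorted ascending; every value of ``rem_sorted`` is present
    in ``cur_sorted``.  Linear merge, O(n + k)."""
    n = len(cur_sorted)
    ri = ai = oi = 0
    for ci in range(n):
        v = cur_sorted[ci]
        if ri < len(rem_sorted) and v == rem_sorted[ri]:
            ri += 1
            continue
        while ai < len(add_sorted) and add_sorted[ai] <= v:
            out[oi] = add_sorted[ai]
            ai += 1
            oi += 1
        out[oi] = v
        oi += 1
    while ai < len(add_sorted):
        out[oi] = add_sorted[ai]
        ai += 1
        oi += 1


@njit(cache=False)
def _fit_kernel(
    pos, dmat, sim_sorted, fixed, real_sorted, proposals, move_idx,
    hc2, d_stop, max_moves, cur_d,
):  # pragma: no cover - exercised via tests
    """Inner loop of the fitted simulation.

    Consumes pre-drawn uniform in-ROI ``proposals`` and particle
    ``move_idx`` streams; mutates ``pos``/``dmat``/``sim_sorted`` in
    place.  A move is kept iff it does not increase the KS distance to
    the real pairwise distances (the asymptotic p is monotone in the
    statistic, so the accept-iff-p-does-not-decrease rule reduces to a
    comparison of D).  The sorted sim-sim distance array is maintained
    incrementally: a move replaces only the k-1 distances involving the
    moved particle.  Returns (moves done, proposals used, current D).
    """
    k = pos.shape[0]
    scratch = np.empty_like(sim_sorted)
    new_row = np.empty(k)
    moves = 0
    prop_ptr = 0
    idx_ptr = 0
    while moves < max_moves and cur_d > d_stop:
        if idx_ptr >= len(move_idx):
            break
        i = move_idx[idx_ptr]
        idx_ptr += 1
        # rejection-sample a hard-core-respecting location for particle i
        ok = False
        px = py = 0.0
        while prop_ptr < len(proposals):
            px = proposals[prop_ptr, 0]
            py = proposals[prop_ptr, 1]
            prop_ptr += 1
            good = True
            for f in range(fixed.shape[0]):
                dx = fixed[f, 0] - px
                dy = fixed[f, 1] - py
                if dx * dx + dy * dy < hc2:
                    good = False
                    break
            if good:
                for q in range(k):
                    if q == i:
                        continue
                    dx = pos[q, 0] - px
                    dy = pos[q, 1] - py
                    if dx * dx + dy * dy < hc2:
                        good = False
                        break
            if good:
                ok = True
                break
        if not ok:
            break  # pool exhausted; caller refills and retries
        for q in range(k):
            dx = pos[q, 0] - px
            dy = pos[q, 1] - py
            new_row[q] = np.sqrt(dx * dx + dy * dy)
        new_row[i] = 0.0
        rem = np.sort(np.concatenate((dmat[i, :i], dmat[i, i + 1 :])))
        add = np.sort(np.concatenate((new_row[:i], new_row[i + 1 :])))
        _replace_sorted(sim_sorted, rem, add, scratch)
        d_new = _ks_stat_merge(real_sorted, scratch)
        moves += 1
        if d_new <= cur_d:  # ties kept
            cur_d = d_new
            pos[i, 0], pos[i, 1] = px, py
            dmat[i, :] = new_row
            dmat[:, i] = new_row
            sim_sorted[:] = scratch
    return moves, prop_ptr, cur_d


def _stop_statistic(ks_alpha: float, en: float) -> float:
    """Largest KS statistic whose asymptotic p is still >= ks_alpha."""
    x = float(kolmogi(ks_alpha))
    while kolmogorov(x) < ks_alpha:  # guard against one-ulp rounding
        x = np.nextafter(x, 0.0)
    return x / en


def fitted_simulation(
    real_xy: np.ndarray,
    roi: ProfileROI | Polygon,
    fixed_xy: np.ndarray | None = None,
    hard_core_nm: float = 10.0,
    ks_alpha: float = 0.1,
    max_iterations: int = 10_000,
    seed: int = 0,
    max_attempts: int = 1_000_000,
    initial_xy: np.ndarray | None = None,
    _sampler: _RoiSampler | None = None,
) -> np.ndarray:
    """Random simulation constrained to match the real pairwise distances.

    ``real_xy`` are the real positions of the simulated class (these also
    fix the particle count).  Starting from a plain random simulation, one
    particle at a time is moved to a fresh uniform hard-core-respecting
    location; the move is reverted iff it makes the sim-sim pairwise
    distance distribution less similar to the real-real one (smaller KS
    p-value); ties are kept.  Iteration stops as soon as p >= ks_alpha
    (checked before the first move, so a start that already satisfies the
    criterion — e.g. ``initial_xy`` set to the real pattern itself —
    returns after zero iterations).

    Raises :class:`FittedNonConvergenceError` (carrying the best p reached)
    after ``max_iterations`` proposed moves.
    """
    real_xy = np.asarray(real_xy, float)
    k = len(real_xy)
    if k < 2:
        raise InsufficientParticlesError("fitted simulation needs >= 2 particles")
    polygon = roi.shapely_polygon() if isinstance(roi, ProfileROI) else roi
    sampler = _sampler if _sampler is not None else _RoiSampler(polygon)
    fixed = np.empty((0, 2)) if fixed_xy is None else np.asarray(fixed_xy, float)
    rng = np.random.default_rng(seed)
    hc2 = hard_core_nm * hard_core_nm

    real_sorted = np.sort(_pdist_flat(real_xy))
    m = len(real_sorted)
    en = np.sqrt(m * m / (2.0 * m))
    d_stop = _stop_statistic(ks_alpha, en)

    if initial_xy is not None:
        pos = np.array(initial_xy, float)
        if pos.shape != (k, 2):
            raise ValueError("initial_xy must match the real particle count")
    else:
        pos = _place_hard_core(k, sampler, fixed, hard_core_nm, rng, max_attempts)
    diff = pos[:, None, :] - pos[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(k, 1)
    sim_sorted = np.sort(dmat[iu])
    cur_d = _ks_stat_sorted(real_sorted, sim_sorted)

    moves_done = 0
    attempts = 0
    while cur_d > d_stop and moves_done < max_iterations:
        chunk = min(max(2048, 2 * (max_iterations - moves_done)), 16384)
        proposals = _draw_uniform_batch(sampler, rng, chunk)
        move_idx = rng.integers(0, k, size=chunk)
        moves, props_used, cur_d = _fit_kernel(
            pos, dmat, sim_sorted, fixed, real_sorted, proposals, move_idx,
            hc2, d_stop, max_iterations - moves_done, cur_d,
        )
        moves_done += moves
        attempts += props_used
        if attempts >= max_attempts:
            raise PackingInfeasibleError(
                f"no valid relocation found after {attempts} proposals"
            )
    if cur_d <= d_stop:
        return pos
    raise FittedNonConvergenceError(
        f"KS p did not reach {ks_alpha} within {max_iterations} iterations",
        float(kolmogorov(en * cur_d)),
    )


def _draw_uniform_batch(sampler: _RoiSampler, rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform in-polygon points, drawn in vectorized rejection batches."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        take = max(n - filled, 1024)
        xs = rng.uniform(sampler.minx, sampler.maxx, take)
        ys = rng.uniform(sampler.miny, sampler.maxy, take)
        inside = shapely.intersects_xy(sampler.polygon, xs, ys)
        pts = np.column_stack([xs[inside], ys[inside]])
        use = min(len(pts), n - filled)
        out[filled : filled + use] = pts[:use]
        filled += use
    return out


def _pdist_flat(xy: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(xy)


# ---------------------------------------------------------------------------
# ensembles


def simulate_ensemble(
    image: ImageRecord,
    roi: ProfileROI,
    sim_class: int,
    mode: str = "random",
    metric: str = "intra_nnd",
    other_class: int | None = None,
    n_sims: int = 500,
    hard_core_nm: float = 10.0,
    ks_alpha: float = 0.1,
    max_fit_iterations: int = 10_000,
    seed: int = 0,
    max_attempts: int = 1_000_000,
):
    """Per-image ensemble of simulated mean NNDs under one null mode.

    Only the ``sim_class`` particles are redistributed; all real particles
    of the other class stay fixed and act as hard-core obstacles.  For
    ``metric='inter_nnd'`` the NND is measured from each simulated
    particle to the nearest fixed real particle of ``other_class``
    (the analysis convention: simulated 5 nm to real 10 nm).
    Per-simulation seeds are derived as ``seed + sim_index``; a fitted
    simulation that fails to converge is retried up to 3 times with fresh
    sub-seeds before the image is flagged by propagating the error.
    """
    from .core_model import SimulationEnsemble

    real = image.particles_of_class(sim_class)
    real_xy = particles_xy(real)
    fixed_particles = [
        p for p in image.particles if p.source == "real" and p.size_class != sim_class
    ]
    fixed_xy = particles_xy(fixed_particles)

    if metric == "intra_nnd":
        if len(real) < 2:
            raise InsufficientParticlesError("intra metric needs >= 2 simulated-class particles")
    elif metric == "inter_nnd":
        if other_class is None:
            raise ValueError("inter metric needs other_class")
        target_xy = particles_xy(
            [p for p in fixed_particles if p.size_class == other_class]
        )
        if len(real) < 1 or len(target_xy) < 1:
            raise InsufficientParticlesError("inter metric needs >= 1 particle of each class")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if mode == "fitted" and len(real) < 2:
        raise InsufficientParticlesError("fitted mode needs >= 2 simulated-class particles")

    polygon = roi.shapely_polygon()
    sampler = _RoiSampler(polygon)
    means = np.empty(n_sims)
    for s in range(n_sims):
        sub_seed = seed + s
        if mode == "random":
            sim_xy = random_simulation(
                len(real), polygon, fixed_xy, hard_core_nm, sub_seed,
                max_attempts, _sampler=sampler,
            )
        elif mode == "fitted":
            last_err: FittedNonConvergenceError | None = None
            sim_xy = None
            for retry in range(4):  # first try + 3 retries with fresh sub-seeds
                try:
                    sim_xy = fitted_simulation(
                        real_xy, polygon, fixed_xy, hard_core_nm, ks_alpha,
                        max_fit_iterations, sub_seed + (retry * 7_654_321) % 2**31,
                        max_attempts, _sampler=sampler,
                    )
                    break
                except FittedNonConvergenceError as err:
                    last_err = err
            if sim_xy is None:
                raise last_err
        else:
            raise ValueError(f"unknown mode {mode!r}")

        if metric == "intra_nnd":
            d = nnd_from_xy(sim_xy, sim_xy, same_set=True)
        else:
            d = nnd_from_xy(sim_xy, target_xy, same_set=False)
        means[s] = d.mean()

    return SimulationEnsemble(
        mode=mode,
        n_sims=n_sims,
        seed=seed,
        sim_mean_nnds=means,
        hard_core_nm=hard_core_nm,
        ks_alpha=ks_alpha if mode == "fitted" else None,
    )
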