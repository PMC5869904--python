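"""Statistical inference on simulation ensembles and density tables.

Per-image association/dissociation verdicts from Monte Carlo rank
p-values, compartment-level two-sided paired t tests with Holm-Bonferroni
correction, and non-parametric density-gradient comparisons
(Kruskal-Wallis omnibus, pairwise Mann-Whitney U, and Dunn's rank-based
multiple comparisons).

Rank p-values use the (k + 1)/(n + 1) convention with ties counted on
both sides (conservative): an image is called associated when its real
mean NND falls in the lowest 2.5% of the simulated mean NNDs and
dissociated when it falls in the highest 2.5% (two-tailed alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_model import AssociationResult, CompartmentResult


@dataclass
class PairedTestInput:
    """Per-image (real mean NND, mean of that image's simulated mean NNDs)."""

    image_id: str
    real_mean_nm: float
    sim_mean_nm: float
    compartment: str = ""
    molecule_pair: str = ""


def per_image_verdict(
    image_id: str,
    real_mean: float,
    sim_means: np.ndarray,
    alpha: float = 0.05,
) -> AssociationResult:
    """Two-tailed Monte Carlo rank test of one image against its ensemble.

    p_low = (1 + #{sim <= real}) / (n + 1), p_high analogous with >=.
    associated iff p_low <= alpha/2; dissociated iff p_high <= alpha/2.
    Requires an ensemble of >= 40 simulations so the 2.5% tail is
    resolvable.
    """
    sims = np.asarray(sim_means, float)
    n = len(sims)
    if n < 40:
        raise ValueError(f"need >= 40 simulations to resolve the tails, got {n}")
    n_lower = int(np.sum(sims <= real_mean))
    n_upper = int(np.sum(sims >= real_mean))
    p_low = (1 + n_lower) / (n + 1)
    p_high = (1 + n_upper) / (n + 1)
    low_sig = p_low <= alpha / 2
    high_sig = p_high <= alpha / 2
    if low_sig and high_sig:
        raise RuntimeError("both tails significant — inconsistent ensemble")
    verdict = "associated" if low_sig else ("dissociated" if high_sig else "ns")
    return AssociationResult(
        image_id=image_id,
        real_mean_nm=float(real_mean),
        n_lower=n_lower,
        n_upper=n_upper,
        verdict=verdict,
        alpha=alpha,
        p_low=p_low,
        p_high=p_high,
    )


def compartment_test(paired_inputs: list[PairedTestInput]) -> tuple[float, float, bool]:
    """Two-sided paired t test of real vs simulated mean NNDs per image.

    Returns (t_statistic, p_raw, degenerate).  All-identical differences
    make the t statistic undefined; such input is reported as p = 1.0 with
    the degenerate flag set rather than an error.
    """
    if len(paired_inputs) < 3:
        raise ValueError(f"paired t test needs >= 3 image pairs, got {len(paired_inputs)}")
    real = np.array([p.real_mean_nm for p in paired_inputs])
    sim = np.array([p.sim_mean_nm for p in paired_inputs])
    diffs = real - sim
    if np.ptp(diffs) == 0:
        return 0.0, 1.0, True
    t, p = stats.ttest_rel(real, sim)
    return float(t), float(p), False


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm adjustment; returns (adjusted p, reject flags).

    adjusted p_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order, mapped back to input positions; rejection iff the
    adjusted p is < alpha.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted, adjusted < alpha


def association_summary(
    per_image: dict[str, list[tuple[PairedTestInput, AssociationResult]]],
    alpha: float = 0.05,
) -> list[CompartmentResult]:
    """Compartment-level summary table from per-image results.

    ``per_image`` maps "(molecule_pair, compartment)"-style keys to that
    group's per-image (paired input, verdict) tuples.  Reports, per group:
    mean +/- SD of real image means and of per-image simulation means,
    the paired t statistic, raw and Holm-adjusted p (the family is the
    set of groups summarised in this one call), and the percentage of
    images individually flagged associated / dissociated.
    """
    keys = sorted(per_image)
    raw_ps, stats_rows = [], []
    for key in keys:
        pairs = [pi for pi, _ in per_image[key]]
        verdicts = [ar.verdict for _, ar in per_image[key]]
        t, p_raw, _ = compartment_test(pairs)
        raw_ps.append(p_raw)
        real = np.array([pi.real_mean_nm for pi in pairs])
        sim = np.array([pi.sim_mean_nm for pi in pairs])
        n = len(pairs)
        stats_rows.append(
            dict(
                key=key,
                n=n,
                real_mean=float(real.mean()),
                real_sd=float(real.std(ddof=1)) if n > 1 else 0.0,
                sim_mean=float(sim.mean()),
                sim_sd=float(sim.std(ddof=1)) if n > 1 else 0.0,
                t=t,
                pct_assoc=100.0 * sum(v == "associated" for v in verdicts) / n,
                pct_dissoc=100.0 * sum(v == "dissociated" for v in verdicts) / n,
            )
        )
    adjusted, _ = holm_bonferroni(raw_ps, alpha) if raw_ps else (np.array([]), None)
    results = []
    for row, p_raw, p_adj in zip(stats_rows, raw_ps, adjusted):
        pair, _, compartment = row["key"].partition(":")
        results.append(
            CompartmentResult(
                compartment=compartment or row["key"],
                molecule_pair=pair,
                n_images=row["n"],
                real_mean_of_means=row["real_mean"],
                real_sd_of_means=row["real_sd"],
                sim_mean_of_means=row["sim_mean"],
                sim_sd_of_means=row["sim_sd"],
                t_statistic=row["t"],
                p_raw=p_raw,
                p_adjusted=float(p_adj),
                pct_associated=row["pct_assoc"],
                pct_dissociated=row["pct_dissoc"],
            )
        )
    return results


@dataclass
class DensityComparison:
    omnibus_p: float
    groups: list[str]
    pairwise_mannwhitney: dict[tuple[str, str], float]  # Holm-adjusted
    pairwise_dunn: dict[tuple[str, str], float]  # stepwise-adjusted Dunn z tests


def density_comparison(groups: dict[str, np.ndarray], alpha: float = 0.05) -> DensityComparison:
    """Compare labelling densities across compartments.

    Kruskal-Wallis omnibus over the groups; the pairwise family is
    reported two ways side by side (the pairing of the two is a matter of
    convention): Mann-Whitney U tests and Dunn's rank-based z tests, each
    with stepwise Holm adjustment across the pairwise family.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("density comparison needs >= 2 groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("every group needs >= 3 records")

    if np.ptp(np.concatenate(arrays)) == 0:
        omnibus_p = 1.0
    else:
        _, omnibus_p = stats.kruskal(*arrays)

    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    # exact U null for small groups (as tabulated), normal approximation above
    mw_raw = [
        float(
            stats.mannwhitneyu(
                groups[a],
                groups[b],
                alternative="two-sided",
                method="exact" if max(len(groups[a]), len(groups[b])) <= 8 else "asymptotic",
            ).pvalue
        )
        for a, b in pairs
    ]
    dunn_raw = _dunn_raw_p(names, arrays, pairs)
    mw_adj, _ = holm_bonferroni(mw_raw, alpha)
    dunn_adj, _ = holm_bonferroni(dunn_raw, alpha)
    return DensityComparison(
        omnibus_p=float(omnibus_p),
        groups=names,
        pairwise_mannwhitney=dict(zip(pairs, mw_adj)),
        pairwise_dunn=dict(zip(pairs, dunn_adj)),
    )


def _dunn_raw_p(names, arrays, pairs) -> list[float]:
    """Dunn's z tests on pooled ranks with tie correction."""
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, arr in zip(names, arrays):
        r = ranks[start : start + len(arr)]
        mean_ranks[name] = r.mean()
        sizes[name] = len(arr)
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    out = []
    for a, b in pairs:
        se = np.sqrt(
            max(n_total * (n_total + 1) / 12.0 - tie_term, 0.0)
            * (1 / sizes[a] + 1 / sizes[b])
        )
        if se == 0.0:  # every pooled value identical
            out.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out.append(float(2 * stats.norm.sf(abs(z))))
    return out
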