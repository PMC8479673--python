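"""MCMC convergence metrics and distribution-comparison utilities.

PSRF follows the modern recommendation: chains are split in half and
rank-normalized before computing the classic between/within variance
ratio, which also catches mixing failures in heavy tails.  ESS combines
per-chain autocorrelations with Geyer's initial-positive-pair truncation.

The comparison utilities summarize a sampled posterior against its
Gaussian prior (KL divergence after moment matching) and compare
predicted against measured concentration distributions (Hellinger
distance, closed form for Gaussian pairs, quadrature otherwise).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "psrf",
    "ess",
    "kl_prior_posterior",
    "hellinger",
    "compare_orthant_distributions",
]


def _check_chains(chains: np.ndarray) -> np.ndarray:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    if chains.ndim != 3:
        raise ValueError("chains must be (n_chains, n_draws) or (n_chains, n_draws, n_dims)")
    if chains.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if chains.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    return chains


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Fractional ranks mapped through the normal quantile function."""
    flat = x.reshape(-1)
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (flat.size + 0.25))
    return z.reshape(x.shape)


def _split(x: np.ndarray) -> np.ndarray:
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def _rhat_1d(x: np.ndarray) -> float:
    c, n = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 1e-300:
        return 1.0 if b <= 1e-300 else np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def psrf(
    chains: np.ndarray,
    rank_normalized: bool = True,
    split: bool = True,
) -> np.ndarray:
    """Potential scale reduction factor per dimension.

    Default is the rank-normalized split version; ``rank_normalized=False``
    gives the plain statistic for comparison.
    """
    chains = _check_chains(chains)
    out = np.empty(chains.shape[2])
    for d in range(chains.shape[2]):
        x = chains[:, :, d]
        if split:
            x = _split(x)
        if rank_normalized:
            x = _rank_normalize(x)
        out[d] = _rhat_1d(x)
    return out


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of a 1-D series via FFT."""
    n = len(x)
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def ess(chains: np.ndarray) -> np.ndarray:
    """Effective sample size per dimension (multi-chain, Geyer-truncated).

    Returns NaN for dimensions with (numerically) zero variance, which
    have no meaningful sample size.
    """
    chains = _check_chains(chains)
    c, n, ndim = chains.shape
    out = np.empty(ndim)
    for d in range(ndim):
        x = chains[:, :, d]
        w = x.var(axis=1, ddof=1).mean()
        means = x.mean(axis=1)
        b_over_n = means.var(ddof=1) if c > 1 else 0.0
        var_hat = (n - 1) / n * w + b_over_n
        if var_hat <= 1e-300 or w <= 1e-300:
            out[d] = np.nan
            continue
        acov = np.mean([_autocov(x[i]) for i in range(c)], axis=0)
        rho = 1.0 - (w - acov) / var_hat
        rho[0] = 1.0
        # Geyer initial positive sequence on pair sums
        tau = 0.0
        t = 1
        prev_pair = np.inf
        while t + 1 < n:
            pair = rho[t] + rho[t + 1]
            if pair < 0:
                break
            pair = min(pair, prev_pair)  # enforce monotone decrease
            tau += pair
            prev_pair = pair
            t += 2
        out[d] = c * n / (1.0 + 2.0 * tau)
    return out


def kl_prior_posterior(
    mu_prior: np.ndarray,
    sd_prior: np.ndarray,
    samples: np.ndarray,
) -> np.ndarray:
    """KL(posterior || prior) per dimension, posterior moment-matched.

    The posterior is summarized as a Gaussian fit to the samples; small
    values flag dimensions whose marginal the constraints barely move.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 100:
        raise ValueError("need at least 100 samples for a stable moment fit")
    mu_prior = np.atleast_1d(np.asarray(mu_prior, dtype=float))
    sd_prior = np.atleast_1d(np.asarray(sd_prior, dtype=float))
    mu_post = samples.mean(axis=0)
    sd_post = samples.std(axis=0, ddof=1)
    if np.any(sd_post <= 0):
        raise ValueError("degenerate sample variance")
    return (
        np.log(sd_prior / sd_post)
        + (sd_post**2 + (mu_post - mu_prior) ** 2) / (2.0 * sd_prior**2)
        - 0.5
    )


def compare_orthant_distributions(
    sampled_table,
    reference_table,
    n_reference: int,
    min_expected: int = 20,
):
    """Per-orthant agreement between a sampled and a reference distribution.

    For orthants whose expected visit count under the reference probability
    is at least ``min_expected`` (the regime where the visit count is
    approximately normal), computes a z-statistic from the combined
    Monte-Carlo standard error; the sampled side's SE is inflated by an
    allowance for the uncertainty of the SE estimate itself, driven by the
    orthant's excursion count when available.  Rarer orthants cannot
    support a per-orthant normal test and are summarized in aggregate.

    Returns a dict with the per-orthant table (``signature``, ``p``,
    ``p_ref``, ``z``), the maximum absolute z, and the aggregate
    probability mass of the unresolvable remainder on both sides.
    """
    import pandas as pd

    sampled = sampled_table.set_index("signature")
    total = int(sampled["count"].sum())
    ref = {tuple(s): float(p) for s, p in
           zip(reference_table["signature"], reference_table["probability"])}
    all_sigs = sorted(set(sampled.index) | set(ref), key=str)
    rows, rem_p, rem_ref = [], 0.0, 0.0
    for sig in all_sigs:
        p_ref = ref.get(sig, 0.0)
        in_sample = sig in sampled.index
        p = float(sampled.loc[[sig], "probability"].iloc[0]) if in_sample else 0.0
        if p_ref * total < min_expected and p * total < min_expected:
            rem_p += p
            rem_ref += p_ref
            continue
        se_s = float(sampled.loc[[sig], "se"].iloc[0]) if in_sample else (
            np.sqrt(p_ref * (1 - p_ref) / total)
        )
        # allowance for the sampled SE being itself an estimate: relative
        # error ~ 1/sqrt(2 E) with E effective independent events
        # (inverted from the regenerative floor se ~ p sqrt(2/E))
        e_proxy = max(2.0 * p**2 / max(se_s**2, 1e-300), 1.0) if p > 0 else 1.0
        se_s *= 1.0 + 1.0 / np.sqrt(2.0 * e_proxy)
        se_ref = np.sqrt(p_ref * (1 - p_ref) / n_reference)
        se = float(np.sqrt(se_s**2 + se_ref**2))
        rows.append(
            {"signature": sig, "p": p, "p_ref": p_ref, "se": se,
             "z": (p - p_ref) / max(se, 1e-12)}
        )
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "max_abs_z": float(table["z"].abs().max()) if len(table) else 0.0,
        "remainder_sampled": rem_p,
        "remainder_reference": rem_ref,
    }


def _as_pdf(dist, grid: np.ndarray) -> np.ndarray:
    kind = dist[0]
    if kind == "gaussian":
        _, mu, sd = dist
        return stats.norm.pdf(grid, mu, sd)
    if kind == "uniform":
        _, lo, hi = dist
        return stats.uniform.pdf(grid, lo, hi - lo)
    if kind == "histogram":
        _, edges, weights = dist
        edges = np.asarray(edges, dtype=float)
        weights = np.asarray(weights, dtype=float)
        dens = weights / (weights.sum() * np.diff(edges))
        idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, len(dens) - 1)
        pdf = dens[idx]
        pdf[(grid < edges[0]) | (grid > edges[-1])] = 0.0
        return pdf
    raise ValueError(f"unknown distribution kind {kind!r}")


def _support(dist) -> tuple[float, float]:
    kind = dist[0]
    if kind == "gaussian":
        _, mu, sd = dist
        return mu - 10 * sd, mu + 10 * sd
    if kind == "uniform":
        return dist[1], dist[2]
    if kind == "histogram":
        edges = np.asarray(dist[1], dtype=float)
        return float(edges[0]), float(edges[-1])
    raise ValueError(f"unknown distribution kind {kind!r}")


def hellinger(dist_a, dist_b, n_grid: int = 20001) -> float:
    """Hellinger distance between two 1-D distributions, in [0, 1].

    Distributions are ``("gaussian", mu, sd)``, ``("uniform", lo, hi)`` or
    ``("histogram", edges, weights)``.  Gaussian pairs use the closed
    form; all other pairs are integrated on a shared grid.  Disjoint
    supports give 1.
    """
    if dist_a[0] == "gaussian" and dist_b[0] == "gaussian":
        _, m1, s1 = dist_a
        _, m2, s2 = dist_b
        s2sum = s1**2 + s2**2
        bc = np.sqrt(2 * s1 * s2 / s2sum) * np.exp(-0.25 * (m1 - m2) ** 2 / s2sum)
        return float(np.sqrt(max(0.0, 1.0 - bc)))
    lo_a, hi_a = _support(dist_a)
    lo_b, hi_b = _support(dist_b)
    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
    if lo >= hi:
        return 1.0
    grid = np.linspace(lo, hi, n_grid)
    pa = _as_pdf(dist_a, grid)
    pb = _as_pdf(dist_b, grid)
    bc = float(np.trapezoid(np.sqrt(pa * pb), grid))
    return float(np.sqrt(max(0.0, 1.0 - min(bc, 1.0))))
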