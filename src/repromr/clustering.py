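"""Mixture-model clustering of per-SNP causal estimates.

Per-SNP Wald ratios theta_i with standard errors s_i are modelled as a
mixture of:

* a **null** component, N(0, s_i^2) — instruments with no effect on the
  outcome;
* k **substantial** components, N(mu_k, s_i^2) — groups of instruments
  sharing a scaled causal effect mu_k;
* a **junk** component, N(0, s_i^2 + tau^2) with a broad tau — outliers that
  group with nothing.

Component means and mixing proportions are estimated by multi-start EM with
the number of substantial clusters chosen by BIC over 0..max_k.  Each SNP
receives posterior assignment probabilities over all components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


__all__ = ["MRClust", "MRClustResults", "fit_mixture", "substantial_members"]


class ClusteringError(ValueError):
    pass


_LOG_2PI = np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _loglik_matrix(theta, se, mus, junk_var):
    """n x (1 + k + 1) matrix of component log densities (null, substantial
    components, junk)."""
    cols = [_norm_logpdf(theta, 0.0, se)]
    for mu in mus:
        cols.append(_norm_logpdf(theta, mu, se))
    cols.append(_norm_logpdf(theta, 0.0, np.sqrt(se**2 + junk_var)))
    return np.column_stack(cols)


def _em(theta, se, k, junk_var, mu_init, *, tol=1e-8, max_iter=1000):
    """EM for fixed k; returns (loglik, mus, pis, responsibilities, n_iter)."""
    n = theta.size
    m = k + 2
    mus = np.asarray(mu_init, float).copy()
    pis = np.full(m, 1.0 / m)
    prev = -np.inf
    w = 1.0 / se**2
    # null and junk log densities do not depend on the EM state
    logdens = np.empty((n, m))
    logdens[:, 0] = _norm_logpdf(theta, 0.0, se)
    logdens[:, -1] = _norm_logpdf(theta, 0.0, np.sqrt(se**2 + junk_var))
    null_junk = logdens[:, [0, -1]].copy()
    half_w = 0.5 * w
    log_se_const = -np.log(se) - 0.5 * _LOG_2PI
    for it in range(max_iter):
        logdens[:, [0, -1]] = null_junk
        if k:
            logdens[:, 1:-1] = (-half_w[:, None]
                                * (theta[:, None] - mus[None, :]) ** 2
                                + log_se_const[:, None])
        logdens += np.log(pis)
        mx = logdens.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logdens - mx).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logdens - lse[:, None])
        pis = resp.mean(axis=0)
        pis = np.clip(pis, 1e-12, None)
        pis /= pis.sum()
        for j in range(k):                     # update substantial means
            r = resp[:, 1 + j]
            denom = np.sum(r * w)
            if denom > 0:
                mus[j] = np.sum(r * w * theta) / denom
        if abs(ll - prev) < tol:
            return ll, mus, pis, resp, it + 1
        prev = ll
    raise ClusteringError(
        f"EM failed to converge after {max_iter} iterations "
        f"(k={k}, last log-likelihood {prev:.6g})")


@dataclass
class MRClustResults:
    """Fitted mixture and per-SNP assignments."""

    k: int                        # number of substantial clusters
    means: np.ndarray             # substantial cluster means
    proportions: np.ndarray       # mixing proportions (null, subst..., junk)
    loglik: float
    bic: float
    probabilities: pd.DataFrame   # per-SNP posterior over components
    assignments: pd.DataFrame     # per-SNP best component + probability
    bic_path: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        labels = ["null"] + [f"substantial_{i+1}" for i in range(self.k)] + ["junk"]
        means = [0.0] + list(self.means) + [0.0]
        counts = self.assignments["cluster"].value_counts()
        return pd.DataFrame({
            "cluster": labels,
            "mean": means,
            "proportion": self.proportions,
            "n_assigned": [int(counts.get(l, 0)) for l in labels],
        })

    def substantial_members(self, threshold: float = 0.80) -> dict:
        return substantial_members(self, threshold=threshold)


class MRClust:
    """Mixture-model clustering of per-SNP ratio estimates.

    Parameters
    ----------
    theta, se : array-like
        Per-SNP causal estimates (Wald ratios) and their SEs.
    variant_ids : sequence of str, optional
    junk_scale : float
        Junk-component variance = ``junk_scale`` * max(max se^2, var(theta));
        default 10.  Tying the junk spread to the sample spread of the
        estimates keeps isolated extreme outliers in the junk component
        rather than letting them earn singleton "substantial" clusters.
    """

    def __init__(self, theta, se, *, variant_ids=None, junk_scale: float = 10.0):
        self.theta = np.asarray(theta, float)
        self.se = np.asarray(se, float)
        if self.theta.size < 5:
            raise ClusteringError("need at least 5 SNPs")
        if (self.se <= 0).any():
            raise ClusteringError("SEs must be positive")
        self.variant_ids = (list(variant_ids) if variant_ids is not None
                            else [f"snp{i}" for i in range(self.theta.size)])
        self.junk_var = junk_scale * float(
            max(np.max(self.se**2), np.var(self.theta, ddof=1)))

    def fit(self, *, max_k: int = 3, seed: int = 0, n_starts: int = 10,
            tol: float = 1e-8, max_iter: int = 1000) -> MRClustResults:
        theta, se = self.theta, self.se
        n = theta.size
        rng = np.random.default_rng(seed)
        best = None
        bic_path = {}
        for k in range(max_k + 1):
            best_k = None
            for start in range(max(1, n_starts if k else 1)):
                if k == 0:
                    mu0 = np.empty(0)
                elif start == 0:
                    # deterministic start: spread over quantiles of theta
                    qs = (np.arange(1, k + 1)) / (k + 1)
                    mu0 = np.quantile(theta, qs)
                else:
                    mu0 = rng.choice(theta, size=k, replace=False)
                try:
                    fitres = _em(theta, se, k, self.junk_var, mu0,
                                 tol=tol, max_iter=max_iter)
                except ClusteringError:
                    continue
                if best_k is None or fitres[0] > best_k[0]:
                    best_k = fitres
            if best_k is None:
                # no start converged for this k: exclude it from selection
                bic_path[k] = None
                continue
            ll = best_k[0]
            n_params = k + (k + 1)          # k means + (k+2-1) free proportions
            bic = -2.0 * ll + n_params * np.log(n)
            bic_path[k] = bic
            if best is None or bic < best[0]:
                best = (bic, k, best_k)

        if best is None:
            raise ClusteringError("EM failed to converge for every candidate k")
        bic, k, (ll, mus, pis, resp, _) = best
        order = np.argsort(mus)             # canonical ordering of clusters
        mus = mus[order]
        col_order = [0] + [1 + int(o) for o in order] + [k + 1]
        resp = resp[:, col_order]
        pis = pis[col_order]
        labels = ["null"] + [f"substantial_{i+1}" for i in range(k)] + ["junk"]
        probs = pd.DataFrame(resp, columns=labels)
        probs.insert(0, "variant_id", self.variant_ids)
        best_idx = resp.argmax(axis=1)
        assignments = pd.DataFrame({
            "variant_id": self.variant_ids,
            "theta": theta,
            "se": se,
            "cluster": [labels[i] for i in best_idx],
            "probability": resp[np.arange(n), best_idx],
            "cluster_mean": [0.0 if i == 0 or i == k + 1 else mus[i - 1]
                             for i in best_idx],
        })
        return MRClustResults(k, mus, pis, ll, bic, probs, assignments,
                              bic_path=bic_path)


def fit_mixture(theta, se, *, variant_ids=None, max_k: int = 3, seed: int = 0,
                junk_scale: float = 10.0, n_starts: int = 10) -> MRClustResults:
    """Functional wrapper around :class:`MRClust`."""
    return MRClust(theta, se, variant_ids=variant_ids,
                   junk_scale=junk_scale).fit(max_k=max_k, seed=seed,
                                              n_starts=n_starts)


def substantial_members(results: MRClustResults, *,
                        threshold: float = 0.80) -> dict:
    """SNPs assigned to each substantial cluster with probability >=
    threshold, with the cluster's effect sign."""
    out = {}
    for i in range(results.k):
        label = f"substantial_{i+1}"
        mask = results.probabilities[label] >= threshold
        out[label] = {
            "mean": float(results.means[i]),
            "sign": "+" if results.means[i] >= 0 else "-",
            "variants": list(results.probabilities.loc[mask, "variant_id"]),
        }
    return out
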