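"""Genotype-dendrophenotype association via three independent models.

* glm_scan     -- per-SNP least-squares regression with Benjamini-Hochberg FDR;
* bslmm_pip    -- sparse Bayesian linear mixed model (spike-slab effects plus a
                  genomic-relationship random effect) sampled by Gibbs, with
                  posterior inclusion probabilities;
* blink_scan   -- iterative pseudo-QTN conditioning with LD exclusion and BIC
                  model selection, Bonferroni-controlled;
* het_associations -- heterozygosity-phenotype correlations and per-population
                  t-tests;
* consensus    -- multi-method intersection sets.

All samplers are seeded; results carry the method name, effect, statistic,
p-value or PIP, the adjusted value and a selection flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dendrogwas.core import GenotypeMatrix

# ---------------------------------------------------------------------------
# helpers


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _complete(y: np.ndarray) -> np.ndarray:
    return np.isfinite(np.asarray(y, float))


# ---------------------------------------------------------------------------
# GLM scan


def glm_scan(
    g: GenotypeMatrix,
    trait: pd.Series | np.ndarray,
    trait_name: str = "trait",
    covariates: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP least-squares scan: trait ~ intercept + dose (+ covariates).

    Two-sided t-test on the allele-dose coefficient, BH adjustment across
    SNPs, selected where adjusted p < fdr.  Trees with missing trait values
    are dropped; effects are per alternate allele in raw trait units.
    """
    y = np.asarray(
        trait.reindex(g.tree_ids) if isinstance(trait, pd.Series) else trait, float
    )
    keep = _complete(y)
    y = y[keep]
    n = len(y)
    n_cov = 0 if covariates is None else covariates.shape[1]
    if n <= n_cov + 2:
        raise ValueError("too few trees with trait values")
    if np.std(y) == 0:
        raise ValueError("constant trait")
    X = g.dosage()[keep]
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    # Frisch-Waugh: residualize trait and dosages on [1, covariates]
    Z = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates)[keep]]
    )
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    sxx = (X_r**2).sum(axis=0)
    sxy = X_r.T @ y_r
    df = n - Z.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, 0.0)
        rss = (y_r**2).sum() - beta * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(np.where(sxx > 0, rss / df / sxx, np.inf))
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.where(sxx > 0, 2 * stats.t.sf(np.abs(t), df), 1.0)
    adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "snp": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "trait": trait_name,
            "method": "GLM",
            "effect": beta,
            "stat": t,
            "p_value": p,
            # <= so the boundary case matches the textbook step-up rule
            "adjusted_p": adj,
            "selected": adj <= fdr,
        }
    )


# ---------------------------------------------------------------------------
# BSLMM

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _bslmm_gibbs(
    Xt, xtx, y, U, evals, n_burn, n_iter, seed, pi_min, pi_max
):  # pragma: no cover - numba-compiled
    np.random.seed(seed)
    p, n = Xt.shape
    gamma = np.zeros(p, np.int8)
    beta = np.zeros(p)
    alpha = np.zeros(n)  # random effect in the eigenbasis of K
    u = np.zeros(n)
    sig_e2 = 0.5
    sig_g2 = 0.1
    sig_b2 = 0.1
    log_pi = np.log(0.01)
    r = y.copy()  # residual y - u - X beta
    pip = np.zeros(p)
    kept = 0
    total = n_burn + n_iter
    for it in range(total):
        # --- spike-slab sweep over SNP effects
        lp_ratio = log_pi - np.log(1.0 - np.exp(log_pi))
        for j in range(p):
            if gamma[j] == 1:
                for i in range(n):
                    r[i] += beta[j] * Xt[j, i]
            xr = 0.0
            for i in range(n):
                xr += Xt[j, i] * r[i]
            var_j = 1.0 / (xtx[j] / sig_e2 + 1.0 / sig_b2)
            mean_j = var_j * xr / sig_e2
            log_odds = lp_ratio + 0.5 * np.log(var_j / sig_b2) \
                + 0.5 * mean_j * mean_j / var_j
            if log_odds > 35.0:
                prob = 1.0
            elif log_odds < -35.0:
                prob = 0.0
            else:
                prob = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < prob:
                gamma[j] = 1
                beta[j] = mean_j + np.sqrt(var_j) * np.random.standard_normal()
                for i in range(n):
                    r[i] -= beta[j] * Xt[j, i]
            else:
                gamma[j] = 0
                beta[j] = 0.0
        # --- polygenic random effect in the eigenbasis
        t_vec = r + u  # y - X beta
        t_rot = U.T @ t_vec
        ssq = 0.0
        n_pos = 0
        for i in range(n):
            lam = evals[i]
            if lam > 1e-8:
                v = lam * sig_g2
                post_var = v * sig_e2 / (v + sig_e2)
                post_mean = v / (v + sig_e2) * t_rot[i]
                alpha[i] = post_mean + np.sqrt(post_var) * np.random.standard_normal()
                ssq += alpha[i] * alpha[i] / lam
                n_pos += 1
            else:
                alpha[i] = 0.0
        u = U @ alpha
        r = t_vec - u
        # --- variances (weak inverse-gamma priors a=b=0.1)
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        sig_e2 = (0.1 + 0.5 * rss) / np.random.gamma(0.1 + 0.5 * n, 1.0)
        sig_g2 = (0.1 + 0.5 * ssq) / np.random.gamma(0.1 + 0.5 * n_pos, 1.0)
        if sig_g2 > 1e4:
            sig_g2 = 1e4
        k_in = 0
        bsq = 0.0
        for j in range(p):
            if gamma[j] == 1:
                k_in += 1
                bsq += beta[j] * beta[j]
        sig_b2 = (0.1 + 0.5 * bsq) / np.random.gamma(0.1 + 0.5 * k_in, 1.0)
        if sig_b2 < 1e-6:
            sig_b2 = 1e-6
        if sig_b2 > 1e4:
            sig_b2 = 1e4
        # --- pi: Metropolis step, log-uniform prior on [pi_min, pi_max]
        prop = log_pi + 0.3 * np.random.standard_normal()
        if prop >= np.log(pi_min) and prop <= np.log(pi_max):
            log_acc = k_in * (prop - log_pi) + (p - k_in) * (
                np.log(1.0 - np.exp(prop)) - np.log(1.0 - np.exp(log_pi))
            )
            if np.log(np.random.random() + 1e-300) < log_acc:
                log_pi = prop
        if it >= n_burn:
            kept += 1
            for j in range(p):
                pip[j] += gamma[j]
    return pip / kept


@dataclass
class BslmmDiagnostics:
    pip_first_half: np.ndarray
    pip_second_half: np.ndarray
    converged: bool


def bslmm_pip(
    g: GenotypeMatrix,
    trait: pd.Series | np.ndarray,
    trait_name: str = "trait",
    n_burn: int = 2000,
    n_iter: int = 10000,
    seed: int = 0,
    pip_threshold: float = 0.25,
    return_diagnostics: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, BslmmDiagnostics]:
    """Sparse Bayesian linear mixed model with posterior inclusion probabilities.

    y = mu + sum_j gamma_j x_j beta_j + u + eps with spike-slab indicators
    gamma_j ~ Bernoulli(pi) (pi log-uniform on [1/p, 0.5]) and a polygenic
    term u ~ N(0, sigma_g^2 K), K the standardized genomic relationship
    matrix.  The trait is standardized; SNP columns are standardized for
    sampling.  PIP_j is the posterior mean of gamma_j; selected where
    PIP > pip_threshold.  A non-convergence flag is raised (warning only)
    when the top-PIP rank order disagrees between chain halves.
    """
    y_raw = np.asarray(
        trait.reindex(g.tree_ids) if isinstance(trait, pd.Series) else trait, float
    )
    keep = _complete(y_raw)
    y = y_raw[keep]
    if np.std(y) == 0:
        raise ValueError("constant trait")
    y = (y - y.mean()) / y.std()
    d = g.dosage()[keep]
    d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    n, p = d.shape
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (d - mu) / sd
    K = (Xs @ Xs.T) / p
    evals, U = np.linalg.eigh(K)
    evals = np.maximum(evals, 0.0)
    Xt = np.ascontiguousarray(Xs.T)
    xtx = (Xs**2).sum(axis=0)
    half = n_iter // 2
    seed32 = int(seed) % (2**31 - 1)
    pip1 = _bslmm_gibbs(Xt, xtx, y, U, evals, n_burn, half, seed32,
                        1.0 / p, 0.5)
    pip2 = _bslmm_gibbs(Xt, xtx, y, U, evals, n_burn, n_iter - half,
                        (seed32 + 1) % (2**31 - 1), 1.0 / p, 0.5)
    pip = (pip1 * half + pip2 * (n_iter - half)) / n_iter
    top1 = set(np.argsort(pip1)[::-1][:5][pip1[np.argsort(pip1)[::-1][:5]] > 0.5])
    top2 = set(np.argsort(pip2)[::-1][:5][pip2[np.argsort(pip2)[::-1][:5]] > 0.5])
    converged = top1 == top2
    res = pd.DataFrame(
        {
            "snp": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "trait": trait_name,
            "method": "BSLMM",
            "effect": np.nan,
            "stat": pip,
            "pip": pip,
            "selected": pip > pip_threshold,
        }
    )
    if return_diagnostics:
        return res, BslmmDiagnostics(pip1, pip2, converged)
    return res


# ---------------------------------------------------------------------------
# BLINK-style iterative scan


def _conditioned_pvalues(
    X: np.ndarray, y: np.ndarray, qtn_idx: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """p-values and effects for every SNP conditioning on the pseudo-QTN set.

    A SNP inside the set is tested conditioning on the other members only.
    """
    n, p = X.shape
    pvals = np.ones(p)
    effects = np.zeros(p)

    def scan(cols: list[int], test_idx: np.ndarray) -> None:
        Z = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
        Q, _ = np.linalg.qr(Z)
        y_r = y - Q @ (Q.T @ y)
        Xs = X[:, test_idx]
        X_r = Xs - Q @ (Q.T @ Xs)
        sxx = (X_r**2).sum(axis=0)
        sxy = X_r.T @ y_r
        df = n - Z.shape[1] - 1
        if df <= 0:
            return
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(sxx > 1e-10, sxy / sxx, 0.0)
            rss = np.maximum((y_r**2).sum() - beta * sxy, 0.0)
            se = np.sqrt(np.where(sxx > 1e-10, rss / df / sxx, np.inf))
            t = np.where(se > 0, beta / se, 0.0)
        pv = np.where(sxx > 1e-10, 2 * stats.t.sf(np.abs(t), df), 1.0)
        pvals[test_idx] = pv
        effects[test_idx] = beta

    non_qtn = np.array([j for j in range(p) if j not in qtn_idx], dtype=int)
    if len(non_qtn):
        scan(qtn_idx, non_qtn)
    for j in qtn_idx:
        scan([q for q in qtn_idx if q != j], np.array([j]))
    return pvals, effects


def blink_scan(
    g: GenotypeMatrix,
    trait: pd.Series | np.ndarray,
    trait_name: str = "trait",
    ld_r2: float = 0.7,
    max_iter: int = 10,
    alpha: float = 0.05,
    max_qtn: int = 20,
) -> pd.DataFrame:
    """Iterative pseudo-QTN association scan with BIC model selection.

    Each round: (1) GLM scan conditioning on the current pseudo-QTN set;
    (2) rank SNPs by p; (3) build a candidate list greedily, skipping SNPs
    with r^2 > ld_r2 to an already-kept candidate; (4) keep the candidate
    prefix minimizing the BIC of trait ~ pseudo-QTNs; (5) repeat until the
    set stabilizes.  Final report: conditioned p-values; selected where
    Bonferroni-corrected p < alpha.
    """
    y_raw = np.asarray(
        trait.reindex(g.tree_ids) if isinstance(trait, pd.Series) else trait, float
    )
    keep = _complete(y_raw)
    y = y_raw[keep]
    if np.std(y) == 0:
        raise ValueError("constant trait")
    X = g.dosage()[keep]
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    n, p = X.shape
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("no polymorphic SNPs")
    sd = X.std(axis=0)
    sd0 = np.where(sd == 0, 1.0, sd)
    Xz = (X - X.mean(axis=0)) / sd0

    qtn: list[int] = []
    cand_thr = alpha / p  # only genome-wide significant SNPs become pseudo-QTNs
    for _ in range(max_iter):
        pvals, _ = _conditioned_pvalues(X, y, qtn)
        order = np.argsort(pvals, kind="stable")
        candidates: list[int] = []
        for j in order:
            if pvals[j] > cand_thr:
                break
            if sd[j] == 0:
                continue
            ok = True
            for c in candidates:
                r2 = (Xz[:, j] @ Xz[:, c] / n) ** 2
                if r2 > ld_r2:
                    ok = False
                    break
            if ok:
                candidates.append(int(j))
            if len(candidates) >= max_qtn:
                break
        # BIC over candidate prefixes
        best_bic, best_m = np.inf, 0
        for m in range(0, len(candidates) + 1):
            cols = candidates[:m]
            Z = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = float(np.sum((y - Z @ coef) ** 2))
            bic = n * np.log(max(rss, 1e-300) / n) + (m + 1) * np.log(n)
            if bic < best_bic:
                best_bic, best_m = bic, m
        new_qtn = sorted(candidates[:best_m])
        if new_qtn == sorted(qtn):
            qtn = new_qtn
            break
        qtn = new_qtn
    pvals, effects = _conditioned_pvalues(X, y, qtn)
    bonf = np.minimum(pvals * p, 1.0)
    return pd.DataFrame(
        {
            "snp": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "trait": trait_name,
            "method": "BLINK",
            "effect": effects,
            "stat": pvals,
            "p_value": pvals,
            "adjusted_p": bonf,
            "selected": bonf < alpha,
            "pseudo_qtn": [j in qtn for j in range(p)],
        }
    )


# ---------------------------------------------------------------------------
# heterozygosity associations


def het_associations(
    het: pd.Series,
    traits: pd.DataFrame,
    populations: pd.Series | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Correlations of individual heterozygosity with every trait, plus
    two-sample Student t-tests of mean heterozygosity per population pair.

    Pearson r and Spearman rho with two-sided p, pairwise-complete per
    trait (traits with < 3 complete pairs are skipped).
    """
    rows = []
    for col in traits.columns:
        joined = pd.concat([het, traits[col]], axis=1, join="inner").dropna()
        if len(joined) < 3:
            continue
        x, y = joined.iloc[:, 0], joined.iloc[:, 1]
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"zero-variance input for trait {col}")
        rp, pp = stats.pearsonr(x, y)
        rs, ps = stats.spearmanr(x, y)
        rows.append(
            {
                "trait": col, "n": len(joined),
                "pearson_r": rp, "pearson_p": pp,
                "spearman_rho": rs, "spearman_p": ps,
                "pearson_significant": pp < alpha,
                "spearman_significant": ps < alpha,
            }
        )
    corr = pd.DataFrame(rows)
    ttests = None
    if populations is not None:
        pops = populations.reindex(het.index)
        labels = list(dict.fromkeys(pops.dropna()))
        trows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a = het[pops == labels[i]]
                b = het[pops == labels[j]]
                t, p = stats.ttest_ind(a, b)
                trows.append(
                    {
                        "pop1": labels[i], "pop2": labels[j],
                        "t": t, "p_value": p, "significant": p < alpha,
                    }
                )
        ttests = pd.DataFrame(trows)
    return corr, ttests


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusSet:
    """Per-method selected SNP sets and their intersections."""

    by_method: dict[str, set[str]]
    pairwise: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    all_methods: set[str] = field(default_factory=set)
    at_least_two: set[str] = field(default_factory=set)

    def membership_table(self) -> pd.DataFrame:
        snps = sorted(set().union(*self.by_method.values()))
        data = {m: [s in sel for s in snps] for m, sel in self.by_method.items()}
        df = pd.DataFrame(data, index=snps)
        df["n_methods"] = df.sum(axis=1)
        return df


def consensus(selected_by_method: dict[str, set[str]]) -> ConsensusSet:
    """Exact intersections of the per-method selected SNP sets."""
    methods = list(selected_by_method)
    cs = ConsensusSet({m: set(s) for m, s in selected_by_method.items()})
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            a, b = methods[i], methods[j]
            cs.pairwise[(a, b)] = cs.by_method[a] & cs.by_method[b]
    if methods:
        cs.all_methods = set.intersection(*cs.by_method.values())
    counts: dict[str, int] = {}
    for s in cs.by_method.values():
        for snp in s:
            counts[snp] = counts.get(snp, 0) + 1
    cs.at_least_two = {s for s, c in counts.items() if c >= 2}
    return cs
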