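"""Population-genomic summaries of a biallelic SNP matrix.

Quality filtering and LD-kNN imputation; per-population diversity (Ho, He,
pi, FIS); pairwise Weir-Cockerham (1984) FST with bootstrap confidence
intervals; Nei's standard genetic distance; hierarchical AMOVA with
permutation tests; allele-frequency PCA; the Mantel test; per-tree
heterozygosity; and great-circle geographic distances between populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dendrogwas.core import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterReport:
    trees_dropped: list[str] = field(default_factory=list)
    snps_dropped_locus_rate: int = 0
    snps_dropped_het: int = 0
    snps_dropped_maf: int = 0

    @property
    def snps_dropped_total(self) -> int:
        return (self.snps_dropped_locus_rate + self.snps_dropped_het
                + self.snps_dropped_maf)


def filter_loci(
    g: GenotypeMatrix,
    min_locus_rate: float = 0.8,
    min_tree_rate: float = 0.8,
    max_obs_het: float = 0.7,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Quality-filter trees then loci, in a fixed, reproducible order.

    1. drop trees with overall call rate < min_tree_rate;
    2. drop SNPs genotyped in < min_locus_rate of the trees of ANY population;
    3. drop SNPs with observed heterozygosity > max_obs_het;
    4. drop SNPs with minor-allele frequency < min_maf
    (het and MAF computed on non-missing calls across all retained trees).
    """
    if g.n_trees == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport()
    called = g.calls != MISSING
    tree_rate = called.mean(axis=1)
    keep_trees = tree_rate >= min_tree_rate
    report.trees_dropped = [t for t, k in zip(g.tree_ids, keep_trees) if not k]
    g = g.take_trees(np.where(keep_trees)[0])
    if g.n_trees == 0:
        raise ValueError("all trees removed by the call-rate filter")

    called = g.calls != MISSING
    keep = np.ones(g.n_snps, dtype=bool)
    for idx in g.pop_index().values():
        rate = called[idx].mean(axis=0)
        keep &= rate >= min_locus_rate
    report.snps_dropped_locus_rate = int((~keep).sum())
    g = g.take_snps(np.where(keep)[0])

    if g.n_snps:
        d = g.dosage()
        with np.errstate(invalid="ignore"):
            ho = np.nanmean(d == 1, axis=0)
        keep = ~(ho > max_obs_het)
        report.snps_dropped_het = int((~keep).sum())
        g = g.take_snps(np.where(keep)[0])

    if g.n_snps:
        maf = g.maf()
        keep = maf >= min_maf  # "not less than" => boundary retained
        report.snps_dropped_maf = int((~keep).sum())
        g = g.take_snps(np.where(keep)[0])

    if g.n_snps == 0:
        raise ValueError("all loci removed by filtering")
    return g, report


# ---------------------------------------------------------------------------
# LD-kNN imputation


def impute_ld_knn(g: GenotypeMatrix, k: int = 5, l: int = 30) -> GenotypeMatrix:
    """LD-kNN imputation of missing calls.

    For each SNP with missing calls, the `l` SNPs in highest LD (r^2,
    computed on mean-filled dosages) define the metric; each missing call is
    replaced by the inverse-distance-weighted vote of the `k` nearest trees
    genotyped at that SNP.  SNPs genotyped in fewer than k trees fall back
    to the most common genotype.
    """
    calls = g.calls.copy()
    miss = calls == MISSING
    if not miss.any():
        return g.copy()
    d = g.dosage()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    filled = np.where(np.isnan(d), col_mean, d).astype(np.float32)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    norms[norms == 0] = 1.0
    standardized = centered / norms
    corr = standardized.T @ standardized  # (p, p) correlation matrix
    r2 = corr**2
    np.fill_diagonal(r2, -1.0)

    n, p = calls.shape
    l_eff = min(l, p - 1)
    for j in np.where(miss.any(axis=0))[0]:
        genotyped = np.where(~miss[:, j])[0]
        targets = np.where(miss[:, j])[0]
        if len(genotyped) < k:
            vals, counts = np.unique(calls[genotyped, j], return_counts=True)
            fill = vals[np.argmax(counts)] if len(vals) else 0
            calls[targets, j] = fill
            continue
        ld_idx = np.argsort(r2[j])[::-1][:l_eff]
        sub = d[:, ld_idx]  # NaN-aware
        for i in targets:
            diff = np.abs(sub[i] - sub[genotyped])
            # distance over pairwise-complete LD SNPs
            with np.errstate(invalid="ignore"):
                dist = np.nanmean(diff, axis=1)
            dist = np.where(np.isfinite(dist), dist, np.inf)
            order = np.argsort(dist, kind="stable")[:k]
            nbrs = genotyped[order]
            w = 1.0 / (dist[order] + 1e-6)
            votes = np.zeros(3)
            for t, wt in zip(nbrs, w):
                votes[calls[t, j]] += wt
            calls[i, j] = int(np.argmax(votes))
    out = g.copy()
    out.calls = calls
    return out


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityStats:
    population: str
    pi: float
    pi_se: float
    ho: float
    ho_se: float
    he: float
    he_se: float
    fis: float
    fis_se: float
    n_snps: int
    pi_per_bp: float | None = None


def _pop_site_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (Ho, He_unbiased, n_called) for one population's calls."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, ((calls == 1) & called).sum(axis=0) / n, np.nan)
        p = np.where(n > 0, np.where(called, calls, 0).sum(axis=0) / (2 * n), np.nan)
        he = 2 * p * (1 - p) * np.where(n > 0.5, 2 * n / (2 * n - 1), np.nan)
    return ho, he, n


def diversity(
    g: GenotypeMatrix, total_length_bp: int | None = None
) -> list[DiversityStats]:
    """Per-population diversity: Ho, unbiased He, per-site pi, FIS.

    He uses the small-sample correction 2p(1-p) * 2n/(2n-1); per-site pi for
    a biallelic site equals that unbiased mean pairwise difference.  FIS =
    1 - Ho/He averaged over sites polymorphic within the population.
    Standard errors are per-locus (sd across SNPs / sqrt(#SNPs)).
    """
    out = []
    for pop, idx in g.pop_index().items():
        if len(idx) < 2:
            raise ValueError(f"population {pop} has fewer than 2 trees")
        ho, he, _ = _pop_site_stats(g.calls[idx])
        pi = he  # per variant site, biallelic
        poly = np.nan_to_num(he) > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            fis_site = 1.0 - ho[poly] / he[poly]

        def mse(x: np.ndarray) -> tuple[float, float]:
            x = x[np.isfinite(x)]
            if len(x) == 0:
                return np.nan, np.nan
            if len(x) == 1:
                return float(x[0]), np.nan
            return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))

        pi_m, pi_s = mse(pi)
        ho_m, ho_s = mse(ho)
        he_m, he_s = mse(he)
        fis_m, fis_s = mse(fis_site) if poly.any() else (np.nan, np.nan)
        out.append(
            DiversityStats(
                pop, pi_m, pi_s, ho_m, ho_s, he_m, he_s, fis_m, fis_s,
                int(np.isfinite(he).sum()),
                pi_per_bp=(float(np.nansum(pi)) / total_length_bp
                           if total_length_bp else None),
            )
        )
    return out


def individual_heterozygosity(g: GenotypeMatrix) -> pd.Series:
    """Heterozygous calls / non-missing calls, per tree."""
    called = g.calls != MISSING
    n = called.sum(axis=1)
    if (n == 0).any():
        bad = [t for t, c in zip(g.tree_ids, n) if c == 0]
        raise ValueError(f"trees with zero genotyped SNPs: {bad}")
    het = (g.calls == 1).sum(axis=1)
    return pd.Series(het / n, index=g.tree_ids, name="heterozygosity")


# ---------------------------------------------------------------------------
# Weir-Cockerham FST


def _wc_components(
    calls_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c for r
    populations (two-allele case)."""
    r = len(calls_by_pop)
    ns, ps, hs = [], [], []
    for calls in calls_by_pop:
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, calls, 0).sum(axis=0) / (2 * n)
            h = ((calls == 1) & called).sum(axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    N = np.array(ns)  # (r, L)
    P = np.array(ps)
    H = np.array(hs)
    nbar = N.sum(axis=0) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (N**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (N * P).sum(axis=0) / (r * nbar)
        s2 = (N * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (N * H).sum(axis=0) / (r * nbar)
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (
            s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    valid = (N > 1).all(axis=0)
    return a[valid], b[valid], c[valid]


def wc_fst(g: GenotypeMatrix, pop1: str, pop2: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations
    (ratio of sums across loci; negative values reported as computed)."""
    idx = g.pop_index()
    a, b, c = _wc_components([g.calls[idx[pop1]], g.calls[idx[pop2]]])
    denom = np.nansum(a + b + c)
    if denom == 0:
        return np.nan
    return float(np.nansum(a) / denom)


def wc_fst_overall(g: GenotypeMatrix) -> float:
    """Multi-locus WC theta over all populations (ratio of sums)."""
    idx = g.pop_index()
    a, b, c = _wc_components([g.calls[i] for i in idx.values()])
    denom = np.nansum(a + b + c)
    if denom == 0:
        return np.nan
    return float(np.nansum(a) / denom)


@dataclass
class PairwiseFstResult:
    populations: list[str]
    fst: pd.DataFrame  # square matrix
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame


def pairwise_fst(
    g: GenotypeMatrix, n_boot: int = 10000, seed: int = 0, ci: float = 0.95
) -> PairwiseFstResult:
    """Pairwise multi-locus WC FST with percentile bootstrap CIs over loci."""
    pops = list(g.pop_index())
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    for p, idx in g.pop_index().items():
        if len(idx) < 2:
            raise ValueError(f"population {p} has fewer than 2 trees")
    m = len(pops)
    fst = np.zeros((m, m))
    lo = np.zeros((m, m))
    hi = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    idx = g.pop_index()
    alpha = (1 - ci) / 2
    for i in range(m):
        for j in range(i + 1, m):
            a, b, c = _wc_components([g.calls[idx[pops[i]]], g.calls[idx[pops[j]]]])
            num, den = np.nan_to_num(a), np.nan_to_num(a + b + c)
            L = len(num)
            theta = num.sum() / den.sum() if den.sum() else np.nan
            fst[i, j] = fst[j, i] = theta
            if n_boot > 0 and L > 0:
                reps = np.empty(n_boot)
                chunk = max(1, min(n_boot, int(5e7 // max(L, 1))))
                done = 0
                while done < n_boot:
                    c_n = min(chunk, n_boot - done)
                    w = rng.multinomial(L, np.full(L, 1.0 / L), size=c_n)
                    reps[done : done + c_n] = (w @ num) / (w @ den)
                    done += c_n
                lo[i, j] = lo[j, i] = np.quantile(reps, alpha)
                hi[i, j] = hi[j, i] = np.quantile(reps, 1 - alpha)
    mk = lambda x: pd.DataFrame(x, index=pops, columns=pops)
    return PairwiseFstResult(pops, mk(fst), mk(lo), mk(hi))


# ---------------------------------------------------------------------------
# Nei's standard genetic distance


def nei_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Nei's (1972) standard genetic distance between populations.

    D = -ln( sum_l Jxy / sqrt(sum_l Jx * sum_l Jy) ) over loci, with
    J the homozygosity/identity sums over the two alleles.  Infinite
    distance (no shared identity) is reported as np.inf.
    """
    idx = g.pop_index()
    pops = list(idx)
    freqs = {}
    for p, rows in idx.items():
        calls = g.calls[rows]
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[p] = np.where(called, calls, 0).sum(axis=0) / (2 * n)
    D = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            p1, p2 = freqs[pops[i]], freqs[pops[j]]
            ok = np.isfinite(p1) & np.isfinite(p2)
            x, y = p1[ok], p2[ok]
            jxy = np.sum(x * y + (1 - x) * (1 - y))
            jx = np.sum(x**2 + (1 - x) ** 2)
            jy = np.sum(y**2 + (1 - y) ** 2)
            if jxy == 0:
                D[i, j] = D[j, i] = np.inf
            else:
                D[i, j] = D[j, i] = -np.log(jxy / np.sqrt(jx * jy))
    return pd.DataFrame(D, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    ss_among_groups: float
    ss_among_pops: float
    ss_within: float
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    fst: float
    fsc: float
    fct: float
    p_fst: float | None = None
    p_fsc: float | None = None
    p_fct: float | None = None

    @property
    def sigma_total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c

    @property
    def percentages(self) -> tuple[float, float, float]:
        """Variance percentages (negative components floored at 0)."""
        a, b, c = (max(self.sigma_a, 0.0), max(self.sigma_b, 0.0),
                   max(self.sigma_c, 0.0))
        tot = a + b + c
        return (100 * a / tot, 100 * b / tot, 100 * c / tot)


def amova_f_indices(
    sigma_a: float, sigma_b: float, sigma_c: float
) -> dict[str, float]:
    """Hierarchical F-indices from the three variance components.

    FST = (sigma_a + sigma_b) / total, FSC = sigma_b / (sigma_b + sigma_c),
    FCT = sigma_a / total; also returns the percentage of variance at each
    level.  Satisfies (1-FCT)(1-FSC) = (1-FST).
    """
    total = sigma_a + sigma_b + sigma_c
    return {
        "FST": (sigma_a + sigma_b) / total,
        "FSC": sigma_b / (sigma_b + sigma_c),
        "FCT": sigma_a / total,
        "pct_among_groups": 100 * sigma_a / total,
        "pct_among_pops": 100 * sigma_b / total,
        "pct_within": 100 * sigma_c / total,
    }


def _amova_components(
    Y: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Variance components of the 3-level nested design on allele counts.

    Y is (n, p) float dosage (no NaN); squared Euclidean distances between
    individuals are the molecular-variance metric.  Returns
    (ss_ag, ss_ap, ss_wp, sigma_a, sigma_b, sigma_c).
    """
    N = len(Y)
    grand = Y.mean(axis=0)
    uniq_groups = np.unique(groups)
    G = len(uniq_groups)
    ss_wp = 0.0
    ss_ap = 0.0
    ss_ag = 0.0
    n_pops_total = 0
    sum_np2_over_ng = 0.0
    sum_np2 = 0.0
    sum_ng2 = 0.0
    for grp in uniq_groups:
        gm = groups == grp
        Yg = Y[gm]
        n_g = len(Yg)
        g_mean = Yg.mean(axis=0)
        ss_ag += n_g * float(np.sum((g_mean - grand) ** 2))
        sum_ng2 += n_g**2
        inner = 0.0
        for pop in np.unique(pops[gm]):
            pm = gm & (pops == pop)
            Yp = Y[pm]
            n_p = len(Yp)
            p_mean = Yp.mean(axis=0)
            ss_wp += float(np.sum((Yp - p_mean) ** 2))
            ss_ap += n_p * float(np.sum((p_mean - g_mean) ** 2))
            inner += n_p**2
            sum_np2 += n_p**2
            n_pops_total += 1
        sum_np2_over_ng += inner / n_g
    P = n_pops_total
    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    sigma_c = ss_wp / df_wp
    if df_ap > 0:
        n1 = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n2 = (sum_np2_over_ng - sum_np2 / N) / df_ag
        n3 = (N - sum_ng2 / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return ss_ag, ss_ap, ss_wp, sigma_a, sigma_b, sigma_c


def amova(
    g: GenotypeMatrix, n_perm: int = 999, seed: int = 0
) -> AmovaResult:
    """Hierarchical AMOVA (groups / populations / individuals).

    Variance components from nested mean squares on squared allele-count
    distances (mean-imputed dosages); permutation p-values use the standard
    schemes: individuals among populations (FST), individuals among
    populations within groups (FSC), whole populations among groups (FCT).
    Falls back to a 2-level design when only one group is present.
    """
    pops = np.asarray(g.populations)
    groups = np.asarray(g.groups)
    for p in np.unique(pops):
        if (pops == p).sum() < 2:
            raise ValueError(f"singleton population {p}")
    d = g.dosage()
    col_mean = np.nanmean(d, axis=0)
    Y = np.where(np.isnan(d), col_mean, d)
    ss_ag, ss_ap, ss_wp, sa, sb, sc = _amova_components(Y, pops, groups)
    total = sa + sb + sc
    fst = (sa + sb) / total if total else 0.0
    fsc = sb / (sb + sc) if (sb + sc) else 0.0
    fct = sa / total if total else 0.0
    res = AmovaResult(ss_ag, ss_ap, ss_wp, sa, sb, sc, fst, fsc, fct)
    if n_perm <= 0:
        return res
    rng = np.random.default_rng(seed)
    multi_group = len(np.unique(groups)) > 1

    def stat_fst(pp, gg):
        _, _, _, a, b, c = _amova_components(Y, pp, gg)
        t = a + b + c
        return (a + b) / t if t else 0.0

    def stat_fsc(pp, gg):
        _, _, _, a, b, c = _amova_components(Y, pp, gg)
        return b / (b + c) if (b + c) else 0.0

    hits_fst = hits_fsc = hits_fct = 0
    pop_of = {}
    uniq_pops = np.unique(pops)
    for p in uniq_pops:
        pop_of[p] = groups[pops == p][0]
    for _ in range(n_perm):
        # FST: individuals permuted among populations over the whole sample
        perm = rng.permutation(len(pops))
        if stat_fst(pops[perm], groups[perm]) >= fst:
            hits_fst += 1
        if multi_group:
            # FSC: individuals permuted among pops within their group
            pp = pops.copy()
            for grp in np.unique(groups):
                gm = np.where(groups == grp)[0]
                pp[gm] = pp[rng.permutation(gm)]
            if stat_fsc(pp, groups) >= fsc:
                hits_fsc += 1
            # FCT: whole populations permuted among groups
            shuffled = rng.permutation([pop_of[p] for p in uniq_pops])
            gg = np.array([dict(zip(uniq_pops, shuffled))[p] for p in pops])
            _, _, _, a, b, c = _amova_components(Y, pops, gg)
            t = a + b + c
            if (a / t if t else 0.0) >= fct:
                hits_fct += 1
    res.p_fst = (hits_fst + 1) / (n_perm + 1)
    if multi_group:
        res.p_fsc = (hits_fsc + 1) / (n_perm + 1)
        res.p_fct = (hits_fct + 1) / (n_perm + 1)
    return res


# ---------------------------------------------------------------------------
# PCA, Mantel, geography


def pca_freq(
    g: GenotypeMatrix, n_components: int = 10, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered (optionally frequency-scaled) genotype matrix.

    Returns per-tree scores and the explained-variance fractions per axis.
    """
    d = g.dosage()
    col_mean = np.nanmean(d, axis=0)
    X = np.where(np.isnan(d), col_mean, d) - col_mean
    if scale:
        p = col_mean / 2.0
        denom = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        X = X / denom
    if not np.any(X):
        raise ValueError("zero-variance genotype matrix")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2
    explained = var / var.sum()
    k = min(n_components, len(S))
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=g.tree_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, explained[:k]


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of distance matrices, permutation p.

    Matrices must share labels, be symmetric with zero diagonals.  p is the
    proportion of label permutations of d2 whose correlation is at least as
    extreme as observed (one-sided "greater" by default, or "two-sided").
    """
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    A = d1.to_numpy(float)
    B = d2.to_numpy(float)
    n = len(A)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    for M in (A, B):
        if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    iu = np.triu_indices(n, 1)

    def corr(M):
        x, y = A[iu], M[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(B)
    if n_perm <= 0:
        return r_obs, np.nan
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = corr(B[np.ix_(perm, perm)])
        if alternative == "two-sided":
            hits += abs(r) >= abs(r_obs)
        else:
            hits += r >= r_obs
    return r_obs, (hits + 1) / (n_perm + 1)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance (km) on the WGS84 mean-radius sphere."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = la2 - la1, lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(popmap: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distances (km) between per-population mean coordinates."""
    if popmap[["latitude", "longitude"]].isna().any().any():
        raise ValueError("missing coordinates in popmap")
    means = popmap.groupby("population", sort=False)[["latitude", "longitude"]].mean()
    pops = list(means.index)
    D = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            D[i, j] = D[j, i] = haversine_km(
                means.iloc[i, 0], means.iloc[i, 1], means.iloc[j, 0], means.iloc[j, 1]
            )
    return pd.DataFrame(D, index=pops, columns=pops)
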