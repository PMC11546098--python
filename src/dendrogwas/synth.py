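"""Synthetic data generator with known ground truth.

Emulates the structure of a dendrogenomic study of six weakly differentiated
conifer populations: a Balding-Nichols SNP matrix, per-tree annual ring-width
series with an age trend, a climate signal, discrete 1-3 year stress periods
and multi-year insect-defoliation episodes, plus planted causal SNPs whose
allele dose modulates growth in stress years.

The generator is first-class, tested code: fixed seed => bit-identical
output, and every planted signal is recorded in a GroundTruth object so
downstream estimators can be scored against it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dendrogwas import io as dio
from dendrogwas.core import Chronology, ClimateSeries, GenotypeMatrix, RingSeries

_POP_NAMES = ["PS", "TK", "ER", "RG", "RS", "SP"]
# two-level hierarchy: the plains population (PS) forms its own group,
# the mountain populations form the other
_POP_GROUPS = {"PS": "plain", "TK": "mountain", "ER": "mountain",
               "RG": "mountain", "RS": "mountain", "SP": "mountain"}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the study design: 6 populations totalling 234 trees,
    weak structure (FST ~ 0.017), thousands of biallelic SNPs with
    MAF >= 0.05, a 90-year span with five short stress periods and one
    six-year defoliation episode affecting a subset of plains-population
    trees.
    """

    n_pops: int = 6
    n_trees_per_pop: list[int] = field(default_factory=lambda: [25, 18, 48, 48, 48, 47])
    n_snps: int = 5000
    target_fst: float = 0.017
    maf_floor: float = 0.05
    n_causal: int = 5
    causal_effect: float = 0.3
    series_span: tuple[int, int] = (1931, 2020)
    stress_years: list[tuple[int, int]] = field(
        default_factory=lambda: [(1937, 1938), (1947, 1947), (1961, 1961),
                                 (1967, 1967), (1988, 1988)]
    )
    stress_multiplier: float = 0.5
    defol_years: list[tuple[int, int]] = field(default_factory=lambda: [(1972, 1977)])
    defol_fraction: float = 0.3
    defol_depression: float = 0.4
    defol_population: str | None = None  # default: first population
    climate_params: dict = field(
        default_factory=lambda: {"t_mean": 10.0, "t_sd": 2.0, "t_amp": 12.0,
                                 "p_mean": 50.0, "p_sd": 15.0}
    )
    climate_month: int = 6
    climate_beta: float = 0.15
    noise_sd: float = 0.15
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_fst", "maf_floor", "defol_fraction",
                     "defol_depression", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.target_fst < 0.5:
            raise ValueError("target_fst must be in [0, 0.5)")
        if len(self.n_trees_per_pop) != self.n_pops:
            raise ValueError("n_trees_per_pop length must equal n_pops")
        if any(n <= 0 for n in self.n_trees_per_pop):
            raise ValueError("sample sizes must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        y0, y1 = self.series_span
        for a, b in list(self.stress_years) + list(self.defol_years):
            if a > b or a < y0 or b > y1:
                raise ValueError(f"period {a}-{b} outside series span {y0}-{y1}")

    @property
    def pop_names(self) -> list[str]:
        if self.n_pops <= len(_POP_NAMES):
            return _POP_NAMES[: self.n_pops]
        return _POP_NAMES + [f"P{i}" for i in range(len(_POP_NAMES), self.n_pops)]


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream estimators."""

    causal_snp_ids: list[str]
    pop_freqs: np.ndarray  # (n_pops, n_snps)
    stress_multipliers: np.ndarray | None = None  # per tree
    defoliated: dict[str, list[str]] | None = None  # episode label -> tree ids


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Balding-Nichols genotype simulation.

    Ancestral frequency p ~ Uniform(maf_floor, 1 - maf_floor); population
    frequency p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F = target_fst
    (p_k = p when F = 0); genotypes ~ Binomial(2, p_k); missing calls
    injected uniformly at missing_rate.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.n_snps)
    F = cfg.target_fst
    if F == 0.0:
        pop_freqs = np.tile(p, (cfg.n_pops, 1))
    else:
        a = p * (1.0 - F) / F
        b = (1.0 - p) * (1.0 - F) / F
        pop_freqs = rng.beta(a, b, size=(cfg.n_pops, cfg.n_snps))
    rows, tree_ids, pops, groups = [], [], [], []
    names = cfg.pop_names
    for k, (name, n_k) in enumerate(zip(names, cfg.n_trees_per_pop)):
        rows.append(rng.binomial(2, pop_freqs[k], size=(n_k, cfg.n_snps)))
        tree_ids += [f"{name}_{i + 1:03d}" for i in range(n_k)]
        pops += [name] * n_k
        groups += [_POP_GROUPS.get(name, "mountain")] * n_k
    calls = np.vstack(rows).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = -1
    chrom = np.array([str(1 + j % 12) for j in range(cfg.n_snps)])
    pos = np.array([1000 + 100 * (j // 12) for j in range(cfg.n_snps)], dtype=np.int64)
    g = GenotypeMatrix(calls, tree_ids, pops, groups, chrom, pos)
    # causal SNPs drawn among reasonably common loci so the planted effect
    # is segregating in every population
    overall = pop_freqs.mean(axis=0)
    common = np.where(np.minimum(overall, 1 - overall) >= 0.2)[0]
    pool = common if len(common) >= cfg.n_causal else np.arange(cfg.n_snps)
    causal_idx = np.sort(rng.choice(pool, size=cfg.n_causal, replace=False))
    truth = GroundTruth(
        causal_snp_ids=[g.snp_ids[i] for i in causal_idx],
        pop_freqs=pop_freqs,
    )
    return g, truth


@dataclass
class SimulatedRings:
    """Ring-width output bundle: host series, climate, non-host chronology."""

    series: list[RingSeries]
    climate: ClimateSeries
    nonhost: Chronology


def _age_trend(age: np.ndarray) -> np.ndarray:
    # negative-exponential juvenile trend levelling at 0.6 mm
    return 1.5 * np.exp(-age / 40.0) + 0.6


def simulate_rings(
    cfg: SimConfig, genotypes: GenotypeMatrix, truth: GroundTruth
) -> SimulatedRings:
    """Multiplicative ring-width model.

    TRW(i, t) = A(age) * C(climate_t) * S(i, t) * eps, where A is a
    negative-exponential age trend, C a linear response to one monthly
    climate variable, S the stress/defoliation multiplier and eps
    lognormal(-sd^2/2, sd).  In stress years the multiplier for tree i is
    ``stress_multiplier * (1 + causal_effect)**dose_i`` (capped at 1), with
    dose_i the summed alternate-allele count over planted causal SNPs, so
    carriers resist the growth depression.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    y0, y1 = cfg.series_span
    years = np.arange(y0, y1 + 1)
    n_years = len(years)

    cp = cfg.climate_params
    months = np.arange(1, 13)
    recs = []
    for y in years:
        t = (cp["t_mean"] - cp["t_amp"] * np.cos(2 * np.pi * (months - 1) / 12)
             + rng.normal(0, cp["t_sd"], 12))
        pr = np.clip(cp["p_mean"] + rng.normal(0, cp["p_sd"], 12), 0, None)
        for m, tv, pv in zip(months, t, pr):
            recs.append((int(y), int(m), float(tv), float(pv)))
    climate = ClimateSeries(
        pd.DataFrame(recs, columns=["year", "month", "temperature", "precipitation"])
    )

    clim = climate.monthly("temperature", cfg.climate_month).reindex(years).to_numpy()
    sd = clim.std()
    z = (clim - clim.mean()) / sd if sd > 0 else np.zeros(n_years)
    C = np.clip(1.0 + cfg.climate_beta * z, 0.2, None)

    causal_j = [genotypes.snp_ids.index(s) for s in truth.causal_snp_ids]
    dose = genotypes.calls[:, causal_j].astype(float)
    dose[dose < 0] = 0.0  # missing causal calls carry no planted effect
    # center the summed dose so the multiplier varies around the base rate
    # instead of saturating at the no-depression ceiling
    dose_sum = dose.sum(axis=1)
    dose_sum -= dose_sum.mean()
    s_tree = np.clip(
        cfg.stress_multiplier * (1.0 + cfg.causal_effect) ** dose_sum, 0.05, 1.0
    )
    truth.stress_multipliers = s_tree

    stress_mask = np.zeros(n_years, dtype=bool)
    for a, b in cfg.stress_years:
        stress_mask[(years >= a) & (years <= b)] = True

    defol_pop = cfg.defol_population or genotypes.populations[0]
    pop_arr = np.asarray(genotypes.populations)
    host_idx = np.where(pop_arr == defol_pop)[0]
    truth.defoliated = {}
    defol_sets = []
    for a, b in cfg.defol_years:
        n_aff = int(round(cfg.defol_fraction * len(host_idx)))
        aff = rng.choice(host_idx, size=n_aff, replace=False) if n_aff else np.array([], int)
        defol_sets.append((a, b, set(aff.tolist())))
        truth.defoliated[f"defol_{a}"] = [genotypes.tree_ids[i] for i in sorted(aff)]

    A = _age_trend(np.arange(n_years, dtype=float))
    series = []
    for i, tid in enumerate(genotypes.tree_ids):
        mult = np.ones(n_years)
        mult[stress_mask] = s_tree[i]
        for a, b, aff in defol_sets:
            if i in aff:
                # stored nutrients buffer the onset year; maximum depression
                # 1-2 years after defoliation, then slow partial recovery
                # while the outbreak persists
                for off, y in enumerate(range(a, b + 1)):
                    profile = 0.8 if off == 0 else max(1.0 - 0.05 * (off - 2), 0.7)
                    if off in (1, 2):
                        profile = 1.0
                    mult[years == y] *= 1.0 - profile * cfg.defol_depression
        if cfg.noise_sd > 0:
            eps = rng.lognormal(-cfg.noise_sd**2 / 2.0, cfg.noise_sd, n_years)
        else:
            eps = np.ones(n_years)
        series.append(RingSeries(tid, years, A * C * mult * eps))

    # non-defoliated reference species: same climate forcing, no stress or
    # defoliation signal; chronology-level noise (mean over ~20 trees, so
    # much tighter than single-tree noise).  The chronology is standardized
    # with the same spline filter as the host indices so host and non-host
    # share identical low-frequency treatment.
    from dendrogwas import treering as _tr

    nh_sd = 0.1 / np.sqrt(20)
    nh_noise = rng.lognormal(-nh_sd**2 / 2, nh_sd, n_years) if cfg.noise_sd > 0 else np.ones(n_years)
    nh_raw = RingSeries("nonhost", years, _age_trend(np.arange(n_years, dtype=float)) * C * nh_noise)
    nh_idx = _tr.detrend_spline(nh_raw)
    nonhost = Chronology(years, nh_idx.indices, np.full(n_years, 20))
    return SimulatedRings(series, climate, nonhost)


def simulate_all(cfg: SimConfig) -> tuple[GenotypeMatrix, GroundTruth, SimulatedRings]:
    """Convenience wrapper: genotypes then rings from a single config."""
    g, truth = simulate_genotypes(cfg)
    rings = simulate_rings(cfg, g, truth)
    return g, truth, rings


def simulate_needles(
    cfg: SimConfig, genotypes: GenotypeMatrix
) -> pd.DataFrame:
    """Per-tree first-year needle lengths (cm): population mean + noise."""
    rng = np.random.default_rng(cfg.seed + 2)
    pop_arr = np.asarray(genotypes.populations)
    base = {p: rng.normal(7.0, 0.5) for p in dict.fromkeys(genotypes.populations)}
    n_needles = 20
    rows = {}
    for i, tid in enumerate(genotypes.tree_ids):
        lens = rng.normal(base[pop_arr[i]], 0.8, n_needles)
        rows[tid] = (float(np.mean(lens)), float(np.var(lens, ddof=1)))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["meanL", "varL"])


def write_fixture_bundle(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    rings: SimulatedRings,
    directory: str | os.PathLike,
    popmap_extra: pd.DataFrame | None = None,
    rwl_dialect: str = "-9999",
) -> dict[str, Path]:
    """Write the full text fixture bundle; round-trips losslessly.

    Emits genotypes.vcf, rings.rwl, rings.csv, climate.csv, popmap.tsv and
    ground_truth.json into `directory` and returns the path map.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": d / "genotypes.vcf",
        "rwl": d / "rings.rwl",
        "rings_csv": d / "rings.csv",
        "climate": d / "climate.csv",
        "popmap": d / "popmap.tsv",
        "truth": d / "ground_truth.json",
        "nonhost": d / "nonhost_chronology.csv",
    }
    dio.write_vcf(genotypes, paths["vcf"])
    dio.write_rwl(rings.series, paths["rwl"], dialect=rwl_dialect)
    dio.write_rings_csv(rings.series, paths["rings_csv"])
    dio.write_climate(rings.climate, paths["climate"])
    pm = pd.DataFrame(
        {
            "tree_id": genotypes.tree_ids,
            "population": genotypes.populations,
            "group": genotypes.groups,
        }
    )
    if popmap_extra is not None:
        pm = pm.merge(popmap_extra, on="tree_id", how="left")
    else:
        # nominal site coordinates: one point per population
        rng = np.random.default_rng(12345)
        coords = {
            p: (52.0 + rng.uniform(-2, 4), 90.0 + rng.uniform(-5, 5), 500 + 300 * i)
            for i, p in enumerate(dict.fromkeys(genotypes.populations))
        }
        pm["latitude"] = [coords[p][0] for p in genotypes.populations]
        pm["longitude"] = [coords[p][1] for p in genotypes.populations]
        pm["elevation"] = [coords[p][2] for p in genotypes.populations]
    dio.write_popmap(pm, paths["popmap"])
    pd.DataFrame(
        {"year": rings.nonhost.years, "value": rings.nonhost.values,
         "depth": rings.nonhost.depth}
    ).to_csv(paths["nonhost"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "causal_snp_ids": truth.causal_snp_ids,
                "pop_freqs": np.round(truth.pop_freqs, 6).tolist(),
                "stress_multipliers": (
                    np.round(truth.stress_multipliers, 6).tolist()
                    if truth.stress_multipliers is not None else None
                ),
                "defoliated": truth.defoliated,
            },
            fh,
            indent=1,
        )
    return paths
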