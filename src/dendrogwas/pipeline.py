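"""End-to-end pipeline orchestration.

A RunConfig (YAML-backed) names the inputs, thresholds, stress periods and
seeds; run_pipeline executes simulate (optional) -> treering -> dendro ->
popgen -> assoc -> annotate, writing every intermediate table plus a JSON
manifest into the run directory.  Each stage is resumable: a completed
stage (marked by its .done sentinel) is skipped on re-run, and resumed
outputs are identical to single-shot outputs because every stage is a pure
function of its inputs and recorded seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dendrogwas import annotate as ann
from dendrogwas import assoc, dendropheno, io as dio, popgen, synth, treering

log = logging.getLogger("dendrogwas")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # inputs (ignored when simulate=True, which generates them)
    simulate: bool = True
    vcf: str | None = None
    popmap: str | None = None
    rings: str | None = None  # .rwl or long csv
    climate: str | None = None
    nonhost: str | None = None  # non-host chronology csv (year,value,depth)
    gff: str | None = None
    # simulation scale
    sim: dict = field(default_factory=dict)
    # analysis knobs
    spline_fraction: float = 0.67
    trend_window: int = 30
    stress_periods: list[dict] = field(
        default_factory=lambda: [
            {"label": "1", "start": 1937, "end": 1938},
            {"label": "2", "start": 1947, "end": 1947},
            {"label": "3", "start": 1961, "end": 1961},
            {"label": "4", "start": 1967, "end": 1967},
            {"label": "5", "start": 1988, "end": 1988},
        ]
    )
    filter: dict = field(default_factory=dict)
    n_boot: int = 1000
    n_perm: int = 199
    methods: list[str] = field(default_factory=lambda: ["glm", "bslmm", "blink"])
    assoc_traits: list[str] | None = None  # default: all Rs/Rt columns
    fdr: float = 0.05
    pip_threshold: float = 0.25
    bslmm_iter: int = 4000
    bslmm_burn: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("vcf", "popmap", "rings"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"{name} is required when simulate is false")
                if not Path(p).exists():
                    raise ConfigError(f"{name} file not found: {p}")
        if self.gff is not None and not Path(self.gff).exists():
            raise ConfigError(f"gff file not found: {self.gff}")
        for sp in self.stress_periods:
            dendropheno.StressPeriod(str(sp["label"]), sp["start"], sp["end"])


def _write_df(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def _stage_done(d: Path, stage: str) -> Path:
    return d / f".{stage}.done"


def run_pipeline(cfg: RunConfig, resume: bool = False) -> Path:
    """Execute the full workflow; returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": {},
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }

    def done(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = [str(p) for p in outputs]
        _stage_done(out, stage).write_text("ok\n")

    # ---- stage: simulate -------------------------------------------------
    fix = out / "fixture"
    if cfg.simulate:
        if not (resume and _stage_done(out, "simulate").exists()):
            log.info("stage simulate")
            sim_cfg = synth.SimConfig(seed=cfg.seed, **cfg.sim)
            g, truth, rings = synth.simulate_all(sim_cfg)
            paths = synth.write_fixture_bundle(g, truth, rings, fix)
            needles = synth.simulate_needles(sim_cfg, g)
            needles.to_csv(fix / "needles.tsv", sep="\t", index_label="tree_id")
            done("simulate", list(paths.values()))
        vcf_path = fix / "genotypes.vcf"
        popmap_path = fix / "popmap.tsv"
        rings_path = fix / "rings.csv"
        nonhost_path = fix / "nonhost_chronology.csv"
        needles_path = fix / "needles.tsv"
    else:
        vcf_path, popmap_path = Path(cfg.vcf), Path(cfg.popmap)
        rings_path = Path(cfg.rings)
        nonhost_path = Path(cfg.nonhost) if cfg.nonhost else None
        needles_path = None

    # ---- load shared inputs ---------------------------------------------
    popmap = dio.read_popmap(popmap_path)
    if str(rings_path).endswith(".rwl"):
        series = dio.read_rwl(rings_path)
    else:
        series = dio.read_rings_csv(rings_path)

    # ---- stage: treering -------------------------------------------------
    if not (resume and _stage_done(out, "treering").exists()):
        log.info("stage treering")
        indexed = [treering.detrend_spline(s, cfg.spline_fraction) for s in series]
        chron = treering.build_chronology(indexed)
        trends = [
            treering.classify_trend(s, cfg.trend_window)
            for s in indexed
            if len(s) >= cfg.trend_window
        ]
        idx_rows = [
            {"tree_id": s.tree_id, "year": int(y), "index": float(v)}
            for s in indexed
            for y, v in zip(s.years, s.indices)
        ]
        _write_df(pd.DataFrame(idx_rows), out / "indices.tsv", index=False)
        _write_df(
            pd.DataFrame(
                {"year": chron.years, "value": chron.values, "depth": chron.depth}
            ),
            out / "chronology.tsv", index=False,
        )
        _write_df(
            pd.DataFrame(
                [
                    {"tree_id": t.tree_id, "slope": t.slope,
                     "p_value": t.p_value, "class": t.trend_class}
                    for t in trends
                ]
            ),
            out / "trends.tsv", index=False,
        )
        done("treering", [out / "indices.tsv", out / "chronology.tsv", out / "trends.tsv"])

    # ---- stage: dendro ---------------------------------------------------
    if not (resume and _stage_done(out, "dendro").exists()):
        log.info("stage dendro")
        periods = [
            dendropheno.StressPeriod(str(sp["label"]), sp["start"], sp["end"])
            for sp in cfg.stress_periods
        ]
        lloret = dendropheno.lloret_trait_table(series, periods)
        needles = (
            pd.read_csv(needles_path, sep="\t", index_col="tree_id")
            if needles_path and Path(needles_path).exists() else None
        )
        desc = dendropheno.descriptive_traits(series, needles)
        traits = lloret.join(desc, how="outer")
        # defoliation reconstruction when a non-host chronology is available
        if nonhost_path and Path(nonhost_path).exists():
            nh = pd.read_csv(nonhost_path)
            nonhost = dendropheno.Chronology(
                nh["year"].to_numpy(), nh["value"].to_numpy(),
                nh.get("depth", pd.Series(np.ones(len(nh)))).to_numpy(),
            )
            indexed = [treering.detrend_spline(s, cfg.spline_fraction) for s in series]
            host_pop = popmap.iloc[0]["population"]
            host_ids = set(popmap[popmap["population"] == host_pop]["tree_id"])
            host = [s for s in indexed if s.tree_id in host_ids]
            events = dendropheno.detect_defoliation(host, nonhost)
            ev_rows = []
            for e in events:
                col = f"defol_{e.event_year}"
                traits[col] = pd.Series(
                    {t: float(v) for t, v in e.response.items()}
                )
                ev_rows.append(
                    {"event_year": e.event_year, "start": e.start_year,
                     "end": e.end_year, "duration": e.duration,
                     "prop_affected": e.prop_affected}
                )
            _write_df(pd.DataFrame(ev_rows), out / "defoliation_events.tsv", index=False)
        _write_df(traits, out / "traits.tsv")
        done("dendro", [out / "traits.tsv"])
    traits = pd.read_csv(out / "traits.tsv", sep="\t", index_col=0, na_values="NA")

    # ---- stage: popgen ---------------------------------------------------
    if not (resume and _stage_done(out, "popgen").exists()):
        log.info("stage popgen")
        g = dio.read_vcf(vcf_path, popmap)
        g, report = popgen.filter_loci(g, **cfg.filter)
        g = popgen.impute_ld_knn(g)
        div = popgen.diversity(g)
        _write_df(
            pd.DataFrame([dataclasses.asdict(d) for d in div]).set_index("population"),
            out / "diversity.tsv",
        )
        fst = popgen.pairwise_fst(g, n_boot=cfg.n_boot, seed=cfg.seed)
        _write_df(fst.fst, out / "pairwise_fst.tsv")
        _write_df(popgen.nei_distance(g), out / "nei_distance.tsv")
        am = popgen.amova(g, n_perm=cfg.n_perm, seed=cfg.seed)
        (out / "amova.json").write_text(
            json.dumps(dataclasses.asdict(am), indent=1, default=float)
        )
        scores, explained = popgen.pca_freq(g)
        _write_df(scores, out / "pca_scores.tsv")
        het = popgen.individual_heterozygosity(g)
        _write_df(het.to_frame(), out / "heterozygosity.tsv")
        if {"latitude", "longitude"}.issubset(popmap.columns) and \
                len(set(popmap["population"])) >= 3:
            geo = popgen.geographic_distance(popmap)
            nei = popgen.nei_distance(g)
            common = [p for p in nei.index if p in geo.index]
            r, pval = popgen.mantel(
                geo.loc[common, common], nei.loc[common, common],
                n_perm=cfg.n_perm, seed=cfg.seed,
            )
            (out / "mantel.json").write_text(
                json.dumps({"r": r, "p": pval}, indent=1)
            )
        # persist the imputed matrix for the assoc stage
        dio.write_vcf(g, out / "filtered_imputed.vcf")
        done("popgen", [out / "diversity.tsv", out / "pairwise_fst.tsv",
                        out / "amova.json", out / "filtered_imputed.vcf"])

    # ---- stage: assoc ----------------------------------------------------
    if not (resume and _stage_done(out, "assoc").exists()):
        log.info("stage assoc")
        g = dio.read_vcf(out / "filtered_imputed.vcf", popmap)
        trait_cols = cfg.assoc_traits or [
            c for c in traits.columns if c.startswith(("Rs", "Rt"))
        ]
        results = []
        selected: dict[str, set[str]] = {m.upper(): set() for m in cfg.methods}
        for col in trait_cols:
            tr = traits[col]
            if tr.dropna().nunique() < 3:
                continue
            if "glm" in cfg.methods:
                r = assoc.glm_scan(g, tr, col, fdr=cfg.fdr)
                results.append(r)
                selected["GLM"] |= set(r.loc[r["selected"], "snp"])
            if "bslmm" in cfg.methods:
                r = assoc.bslmm_pip(
                    g, tr, col, n_burn=cfg.bslmm_burn, n_iter=cfg.bslmm_iter,
                    seed=cfg.seed, pip_threshold=cfg.pip_threshold,
                )
                results.append(r)
                selected["BSLMM"] |= set(r.loc[r["selected"], "snp"])
            if "blink" in cfg.methods:
                r = assoc.blink_scan(g, tr, col)
                results.append(r)
                selected["BLINK"] |= set(r.loc[r["selected"], "snp"])
        if results:
            _write_df(pd.concat(results, ignore_index=True),
                      out / "associations.tsv", index=False)
        cs = assoc.consensus(selected)
        _write_df(cs.membership_table(), out / "consensus.tsv")
        (out / "consensus.json").write_text(
            json.dumps(
                {
                    "by_method": {m: sorted(s) for m, s in cs.by_method.items()},
                    "at_least_two": sorted(cs.at_least_two),
                    "all_methods": sorted(cs.all_methods),
                },
                indent=1,
            )
        )
        done("assoc", [out / "associations.tsv", out / "consensus.tsv"])

    # ---- stage: annotate -------------------------------------------------
    if cfg.gff and not (resume and _stage_done(out, "annotate").exists()):
        log.info("stage annotate")
        genes = ann.load_gff(cfg.gff)
        cons = json.loads((out / "consensus.json").read_text())
        snp_set = set(cons["at_least_two"]) | set(cons["all_methods"])
        g = dio.read_vcf(out / "filtered_imputed.vcf", popmap)
        lookup = {s: (c, int(p)) for s, c, p in zip(g.snp_ids, g.chrom, g.pos)}
        todo = [(s, *lookup[s]) for s in sorted(snp_set) if s in lookup]
        annos = ann.annotate_snps(todo, genes)
        _write_df(
            pd.DataFrame([dataclasses.asdict(a) for a in annos]),
            out / "snp_annotation.tsv", index=False,
        )
        done("annotate", [out / "snp_annotation.tsv"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
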