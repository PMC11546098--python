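"""Readers and writers for the pipeline's on-disk formats.

Tucson .rwl (decadal layout), plain-text VCF 4.2, long-format ring CSV,
monthly climate CSV, population-map TSV and trait-table TSV.  The .rwl
parser supports both common dialects: widths in 0.01 mm terminated by a
``999`` stop marker, and widths in 0.001 mm terminated by ``-9999``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from dendrogwas.core import ClimateSeries, GenotypeMatrix, RingSeries

# ---------------------------------------------------------------------------
# Tucson .rwl


def write_rwl(series: list[RingSeries], path: str | os.PathLike, dialect: str = "-9999") -> None:
    """Write ring series in decadal Tucson layout.

    dialect "-9999": widths stored as 0.001 mm integers, stop marker -9999;
    dialect "999":   widths stored as 0.01 mm integers, stop marker 999.
    """
    if dialect == "-9999":
        scale, stop = 1000, -9999
    elif dialect == "999":
        scale, stop = 100, 999
    else:
        raise ValueError("dialect must be '-9999' or '999'")
    lines = []
    for s in series:
        sid = s.tree_id[:8]
        vals = np.round(s.widths * scale).astype(int)
        year = s.first_year
        # decade rows: first row starts at the series' first year
        pos = 0
        while pos < len(vals):
            decade = year - year % 10
            row_end = min(len(vals), pos + (decade + 10 - year))
            row = vals[pos:row_end].tolist()
            last_row = row_end == len(vals)
            if last_row and len(row) < 10:
                row.append(stop)
            lines.append(f"{sid:<8}{year:>4}" + "".join(f"{v:>6}" for v in row))
            if last_row and len(row) == 10 and row[-1] != stop:
                # stop marker spills to its own row
                lines.append(f"{sid:<8}{year + len(row):>4}{stop:>6}")
            pos = row_end
            year = decade + 10
    Path(path).write_text("\n".join(lines) + "\n")


def read_rwl(path: str | os.PathLike, dialect: str = "-9999") -> list[RingSeries]:
    """Parse a decadal Tucson .rwl file back into RingSeries."""
    if dialect == "-9999":
        scale, stop = 1000.0, -9999
    elif dialect == "999":
        scale, stop = 100.0, 999
    else:
        raise ValueError("dialect must be '-9999' or '999'")
    data: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        year = int(raw[8:12])
        if sid not in data:
            data[sid] = []
            order.append(sid)
        body = raw[12:]
        vals = []
        for i in range(0, len(body), 6):
            tok = body[i : i + 6].strip()
            if tok:
                vals.append(int(tok))
        for j, v in enumerate(vals):
            if v == stop:
                break
            data[sid].append((year + j, v))
    out = []
    for sid in order:
        pairs = sorted(data[sid])
        years = np.array([y for y, _ in pairs])
        widths = np.array([w for _, w in pairs], dtype=float) / scale
        out.append(RingSeries(sid, years, widths))
    return out


# ---------------------------------------------------------------------------
# long-format ring CSV


def write_rings_csv(series: list[RingSeries], path: str | os.PathLike) -> None:
    rows = []
    for s in series:
        for y, w in zip(s.years, s.widths):
            rows.append((s.tree_id, int(y), float(w)))
    pd.DataFrame(rows, columns=["tree_id", "year", "width_mm"]).to_csv(path, index=False)


def read_rings_csv(path: str | os.PathLike) -> list[RingSeries]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("tree_id", sort=False):
        sub = sub.sort_values("year")
        out.append(RingSeries(str(tid), sub["year"].to_numpy(), sub["width_mm"].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# VCF

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Emit a minimal plain-text VCF 4.2 with biallelic SNPs and GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.tree_ids)
            + "\n"
        )
        for j in range(g.n_snps):
            gts = "\t".join(_GT_STR[int(v)] for v in g.calls[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | os.PathLike,
    popmap: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix via cyvcf2.

    If a popmap table (tree_id, population[, group]) is given, population and
    group labels are joined on sample id; otherwise all samples form one
    population.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}.{var.POS}")
        gt = var.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append(dose.astype(np.int8))
    vcf.close()
    calls = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    if popmap is not None:
        pm = popmap.set_index("tree_id")
        pops = [str(pm.loc[s, "population"]) for s in samples]
        groups = (
            [str(pm.loc[s, "group"]) for s in samples] if "group" in pm.columns else None
        )
    else:
        pops, groups = ["pop1"] * len(samples), None
    return GenotypeMatrix(
        calls, samples, pops, groups, np.array(chroms), np.array(poss), ids
    )


# ---------------------------------------------------------------------------
# simple tables


def write_popmap(popmap: pd.DataFrame, path: str | os.PathLike) -> None:
    popmap.to_csv(path, sep="\t", index=False)


def read_popmap(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tree_id": str})
    if "tree_id" not in df.columns or "population" not in df.columns:
        raise ValueError("popmap needs at least tree_id and population columns")
    return df


def write_climate(climate: ClimateSeries, path: str | os.PathLike) -> None:
    climate.table.to_csv(path, index=False)


def read_climate(path: str | os.PathLike) -> ClimateSeries:
    return ClimateSeries(pd.read_csv(path))


def write_traits(traits: pd.DataFrame, path: str | os.PathLike) -> None:
    traits.to_csv(path, sep="\t", index=True, index_label="tree_id", na_rep="NA")


def read_traits(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="tree_id", na_values="NA")
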