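"""File formats: phenotype/pool-manifest/read-count TSVs, VCF, BED.

Conventions are centralised here: VCF positions are 1-based, BED
intervals 0-based half-open, and site keys are ``chrom:pos:ref:alt``
with 1-based positions.  All tables round-trip byte-identically, and a
run manifest records seeds and SHA-256 hashes of every written file so
reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .pools import Pool, PoolDesign

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_pool_manifest",
    "write_pool_manifest",
    "read_read_counts",
    "write_read_counts",
    "write_variant_vcf",
    "read_variant_vcf",
    "read_bed",
    "write_bed",
    "bed_interval_to_vcf_pos",
    "vcf_pos_to_bed_interval",
    "parse_site_key",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed input line; message carries the file and line number."""


def parse_site_key(site: str) -> tuple[str, int, str, str]:
    """Split a ``chrom:pos:ref:alt`` site key (1-based position)."""
    parts = site.split(":")
    if len(parts) != 4:
        raise FormatError(f"bad site key {site!r}: expected chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


def bed_interval_to_vcf_pos(start: int) -> int:
    """0-based half-open BED start -> 1-based VCF position."""
    return start + 1


def vcf_pos_to_bed_interval(pos: int, ref_len: int = 1) -> tuple[int, int]:
    """1-based VCF position -> 0-based half-open BED interval."""
    return pos - 1, pos - 1 + ref_len


# --- simple TSV tables -----------------------------------------------


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")


def write_phenotypes(individuals: pd.DataFrame, path) -> None:
    out = individuals[["id", "status", "age_at_diagnosis"]].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.1f")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "status": str})
    _require_columns(df, {"id", "status", "age_at_diagnosis"}, path)
    bad = df.index[~df["status"].isin(["case", "control"])]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 2}: bad status {df.loc[bad[0], 'status']!r}")
    df["onset_group"] = np.where(
        df["status"] == "control",
        "control",
        np.where(df["age_at_diagnosis"] < 40, "early", "late"),
    )
    return df


def write_pool_manifest(design: PoolDesign, path) -> None:
    rows = [
        {
            "pool_id": p.pool_id,
            "stage": p.stage,
            "stratum": p.stratum,
            "members": ",".join(p.members),
        }
        for p in design.pools
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pool_manifest(path) -> PoolDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, {"pool_id", "stage", "stratum", "members"}, path)
    pools = []
    for i, row in df.iterrows():
        members = tuple(m for m in str(row["members"]).split(",") if m)
        if not members:
            raise FormatError(f"{path}: line {i + 2}: pool {row['pool_id']} has no members")
        pools.append(
            Pool(
                pool_id=row["pool_id"],
                stage=int(row["stage"]),
                stratum=row["stratum"],
                members=members,
            )
        )
    return PoolDesign(pools)


def write_read_counts(counts: pd.DataFrame, path) -> None:
    counts[["pool_id", "site", "depth", "alt_count"]].to_csv(path, sep="\t", index=False)


def read_read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "site": str})
    _require_columns(df, {"pool_id", "site", "depth", "alt_count"}, path)
    if (df["alt_count"] > df["depth"]).any():
        i = int(df.index[df["alt_count"] > df["depth"]][0])
        raise FormatError(f"{path}: line {i + 2}: alt_count exceeds depth")
    return df


# --- VCF --------------------------------------------------------------


def write_variant_vcf(
    variant_table: pd.DataFrame,
    calls: pd.DataFrame,
    path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write discovered variants as an uncompressed VCF.

    One "sample" per pool; the ``PC`` FORMAT field carries the per-pool
    estimated allele count and ``DP`` the pool depth.  Cohort AC/AN/AF
    live in INFO.  Positions are 1-based, straight from the site keys.
    """
    pools = sorted(calls["pool_id"].unique())
    sites = list(variant_table.index)
    parsed = [parse_site_key(s) for s in sites]
    if contig_lengths is None:
        contig_lengths = {}
        for chrom, pos, _, _ in parsed:
            contig_lengths[chrom] = max(contig_lengths.get(chrom, 0), pos + 1000)
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("AC", "A", "Integer", "Estimated cohort alt allele count")
    header.info.add("AN", 1, "Integer", "Chromosomes in depth-passing pools")
    header.info.add("AF", "A", "Float", "Cohort alt allele frequency")
    header.formats.add("PC", 1, "Integer", "Estimated pool alt allele count")
    header.formats.add("DP", 1, "Integer", "Pool read depth")
    for p in pools:
        header.add_sample(p)
    by_pool_site = calls.set_index(["pool_id", "site"])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        order = sorted(range(len(sites)), key=lambda k: (parsed[k][0], parsed[k][1]))
        for k in order:
            chrom, pos, ref, alt = parsed[k]
            site = sites[k]
            row = variant_table.loc[site]
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), id=site.replace(":", "_")
            )
            rec.info["AC"] = (int(row["AC"]),)
            rec.info["AN"] = int(row["AN"])
            rec.info["AF"] = (float(row["AF"]),)
            for p in pools:
                try:
                    call = by_pool_site.loc[(p, site)]
                    rec.samples[p]["PC"] = int(call["est_count"])
                    rec.samples[p]["DP"] = int(call["depth"])
                except KeyError:
                    pass
            vcf.write(rec)


def read_variant_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF written by :func:`write_variant_vcf`.

    Returns (variant table indexed by site, long per-pool count frame).
    """
    rows, call_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        pools = list(vcf.header.samples)
        for rec in vcf:
            site = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            def _scalar(v):
                return v[0] if isinstance(v, tuple) else v

            rows.append(
                {
                    "site": site,
                    "AC": _scalar(rec.info["AC"]),
                    "AN": _scalar(rec.info["AN"]),
                    "AF": _scalar(rec.info["AF"]),
                }
            )
            for p in pools:
                pc = rec.samples[p].get("PC")
                if pc is not None:
                    call_rows.append(
                        {
                            "pool_id": p,
                            "site": site,
                            "est_count": pc,
                            "depth": rec.samples[p].get("DP"),
                        }
                    )
    table = pd.DataFrame(rows).set_index("site") if rows else pd.DataFrame()
    return table, pd.DataFrame(call_rows)


# --- BED --------------------------------------------------------------


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write target regions (columns chrom, start, end, name) as BED;
    starts are 0-based half-open."""
    regions[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    if (df["end"] <= df["start"]).any():
        i = int(df.index[df["end"] <= df["start"]][0])
        raise FormatError(f"{path}: line {i + 1}: end must exceed start")
    return df


# --- manifests --------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir, files: list[str], seeds: dict[str, int]) -> Path:
    """Record seeds and SHA-256 hashes of the run's outputs."""
    outdir = Path(outdir)
    manifest = {
        "seeds": seeds,
        "files": {f: _sha256(outdir / f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
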