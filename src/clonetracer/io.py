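"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel as multi-sample VCF (alt/total depths in the AD/DP
FORMAT fields, positions 1-based) or flat TSV; copy-number segments as
BED-like TSV (0-based half-open on disk, converted to/from the 1-based
inclusive convention used internally for point lookups); sample metadata as
TSV; simulation truth and trees as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

VARIANT_COLUMNS = [
    "variant_id", "sample_id", "chrom", "pos", "ref", "alt",
    "alt_count", "depth", "is_indel", "context",
]


class VariantParseError(ValueError):
    pass


def read_variants(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a variant table from VCF or TSV into the long per-sample layout."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "context"]
        if missing:
            raise VariantParseError(f"{path}: missing columns {missing}")
        return df
    raise ValueError(f"unknown variant format: {fmt}")


def _read_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise VariantParseError(f"{path}: record {i} (line offset) is not biallelic")
            alt = rec.alts[0]
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            ctx = rec.info.get("CTX", None)
            if isinstance(ctx, tuple):
                ctx = ctx[0]
            for s in samples:
                fmt = rec.samples[s]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                if ad is None or dp is None:
                    raise VariantParseError(
                        f"{path}: record {i} sample {s} lacks AD/DP depth fields"
                    )
                rows.append(
                    {
                        "variant_id": vid,
                        "sample_id": s,
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "alt_count": int(ad[1]),
                        "depth": int(dp),
                        "is_indel": len(rec.ref) != 1 or len(alt) != 1,
                        "context": ctx,
                    }
                )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants_vcf(variants: pd.DataFrame, path: str | Path, contig_len: int = 2**29) -> None:
    """Write the long variant table as one multi-sample VCF."""
    path = Path(path)
    header = pysam.VariantHeader()
    for chrom in pd.unique(variants.chrom):
        header.contigs.add(str(chrom), length=contig_len)
    header.info.add("CTX", 1, "String", "Trinucleotide context on the + strand")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    samples = list(pd.unique(variants.sample_id))
    for s in samples:
        header.add_sample(s)

    wide_alt = variants.pivot(index="variant_id", columns="sample_id", values="alt_count")
    wide_dep = variants.pivot(index="variant_id", columns="sample_id", values="depth")
    meta = variants.drop_duplicates("variant_id").set_index("variant_id")
    order = meta.sort_values(["chrom", "pos"]).index

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for vid in order:
            m = meta.loc[vid]
            rec = out.new_record(
                contig=str(m.chrom),
                start=int(m.pos) - 1,
                stop=int(m.pos) - 1 + len(str(m.ref)),
                alleles=(str(m.ref), str(m.alt)),
                id=str(vid),
            )
            if isinstance(m.context, str):
                rec.info["CTX"] = m.context
            for s in samples:
                dp = int(wide_dep.loc[vid, s])
                ad = int(wide_alt.loc[vid, s])
                rec.samples[s]["AD"] = (dp - ad, ad)
                rec.samples[s]["DP"] = dp
            out.write(rec)


def read_segments(path: str | Path) -> pd.DataFrame:
    """BED-like segment TSV (0-based half-open starts on disk)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required <= set(df.columns):
        raise VariantParseError(f"{path}: segment table needs columns {sorted(required)}")
    return df


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(o)}")


def truth_to_json(truth) -> dict:
    return {
        "root": truth.root,
        "parent": {str(k): v for k, v in truth.parent.items()},
        "purity_true": truth.purity_true.to_dict(),
        "ploidy_true": truth.ploidy_true.to_dict(),
        "ccf_true": {s: truth.ccf_true.loc[s].to_dict() for s in truth.ccf_true.index},
        "clone_fraction": {
            s: truth.clone_fraction.loc[s].to_dict() for s in truth.clone_fraction.index
        },
        "assignment": truth.assignment.to_dict(),
        "multiplicity": truth.multiplicity.to_dict(),
        "dominant_branch": truth.dominant_branch,
        "fluid_mixtures": truth.fluid_mixtures,
    }
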