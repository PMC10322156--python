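"""Plain-text I/O: frequency tables, genotype matrices, reference
tables, ancestry/ROH tracks (BED-like, cM coordinates) and results JSON.

All tabular formats are TSV with documented headers; intervals are
0-based half-open.  Results JSON embeds the seed and a configuration
hash so runs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .roh import AncestryROHTrack, AncestrySegment, ROHInterval
from .sumstats import SUMMARY_NAMES

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "vcf_to_frequency_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_reference_table",
    "write_reference_table",
    "read_summary_vector",
    "write_summary_vector",
    "read_tracks",
    "write_tracks",
    "config_hash",
    "write_results_json",
]


def write_frequency_table(path, frequencies: np.ndarray,
                          snp_ids: Optional[Sequence[str]] = None) -> None:
    """Two-column TSV: snp_id, freq."""
    freqs = np.asarray(frequencies, dtype=float)
    ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(freqs.size)]
    pd.DataFrame({"snp_id": ids, "freq": freqs}).to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> tuple[np.ndarray, list]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frequency table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "freq"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns snp_id, freq")
    return df["freq"].to_numpy(dtype=float), df["snp_id"].tolist()


def vcf_to_frequency_table(vcf_path, out_path) -> int:
    """Convert biallelic sites of a VCF into a snp_id/freq TSV.

    Returns the number of sites written; requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    ids, freqs = [], []
    for var in VCF(str(vcf_path)):
        if len(var.ALT) != 1:
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        freqs.append(var.aaf)
    write_frequency_table(out_path, np.array(freqs), ids)
    return len(ids)


def write_genotype_matrix(path, genotypes: np.ndarray,
                          individual_ids: Optional[Sequence[str]] = None,
                          snp_ids: Optional[Sequence[str]] = None) -> None:
    """TSV with individual ids as the first column, SNP ids as header."""
    g = np.asarray(genotypes)
    inds = individual_ids or [f"ind{i}" for i in range(g.shape[0])]
    snps = snp_ids or [f"snp{j}" for j in range(g.shape[1])]
    pd.DataFrame(g, index=pd.Index(inds, name="individual"), columns=snps).to_csv(
        path, sep="\t"
    )


def read_genotype_matrix(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype matrix not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=np.uint8)


def write_reference_table(path, table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# admixture-history ABC reference table\n")
        fh.write("# columns: scenario, parameter columns (NA where a parameter "
                 "is absent from a scenario), then the 42 summary statistics\n")
        table.to_csv(fh, sep="\t", index=False)


def read_reference_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference table not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def write_summary_vector(path, vector: np.ndarray) -> None:
    pd.DataFrame([vector], columns=list(SUMMARY_NAMES)).to_csv(
        path, sep="\t", index=False
    )


def read_summary_vector(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_NAMES if c not in df.columns]
    if missing or len(df) < 1:
        raise ValueError(f"summary vector file lacks columns {missing[:3]}")
    return df[list(SUMMARY_NAMES)].iloc[0].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# ancestry/ROH tracks


def write_tracks(path, tracks: Sequence[AncestryROHTrack]) -> None:
    """BED-like TSV holding every individual's ancestry segments and ROH.

    Columns: individual, record (ancestry|roh), chrom, start_cM, end_cM,
    label, haplotype; chromosome lengths in `#map` header lines.
    """
    with open(path, "w") as fh:
        maps = tracks[0].chrom_lengths
        for c, L in maps.items():
            fh.write(f"#map\t{c}\t{L}\n")
        fh.write("individual\trecord\tchrom\tstart_cM\tend_cM\tlabel\thaplotype\n")
        for i, t in enumerate(tracks):
            if t.chrom_lengths != maps:
                raise ValueError("all tracks must share one chromosome map")
            for s in t.segments:
                fh.write(
                    f"ind{i}\tancestry\t{s.chrom}\t{s.start:.6f}\t{s.end:.6f}"
                    f"\t{s.ancestry}\t{s.haplotype}\n"
                )
            for r in t.roh:
                fh.write(
                    f"ind{i}\troh\t{r.chrom}\t{r.start:.6f}\t{r.end:.6f}\t.\t.\n"
                )


def read_tracks(path) -> list:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"track file not found: {path}")
    chrom_lengths = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#map\t"):
                _, c, L = line.rstrip("\n").split("\t")
                chrom_lengths[c] = float(L)
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if not chrom_lengths:
        raise ValueError("track file lacks #map header lines")
    tracks = []
    for _, sub in df.groupby("individual", sort=False):
        segs = [
            AncestrySegment(
                haplotype=int(r.haplotype), chrom=str(r.chrom),
                start=float(r.start_cM), end=float(r.end_cM),
                ancestry=str(r.label),
            )
            for r in sub[sub.record == "ancestry"].itertuples()
        ]
        roh = [
            ROHInterval(chrom=str(r.chrom), start=float(r.start_cM),
                        end=float(r.end_cM))
            for r in sub[sub.record == "roh"].itertuples()
        ]
        tracks.append(AncestryROHTrack(chrom_lengths=dict(chrom_lengths),
                                       segments=segs, roh=roh))
    return tracks


# ---------------------------------------------------------------------------
# results


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results_json(path, payload: dict, seed: int, config: dict) -> None:
    from . import __version__

    out = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "version": __version__,
        **payload,
    }

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        if isinstance(o, (pd.DataFrame,)):
            return o.to_dict()
        return str(o)

    Path(path).write_text(json.dumps(out, indent=2, default=default))
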