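"""On-disk formats: metadata-headed TSV dialects and PLINK bed/bim/fam.

Every TSV starts with ``#``-prefixed ``key: value`` header lines (config
hash, seed, stage) followed by a tab-separated table; floats are printed
with ``%.10g`` so equal runs produce byte-identical files.

The PLINK writer/reader implements the SNP-major 2-bit .bed codec directly
(dosage of the bim A1 allele: 00->2, 10->1, 11->0, 01->missing).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .phenogrid import CASE, CONTROL
from .simgen import INTERNAL_TRAITS, ComponentTable, GenotypePanel

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_component_table",
    "read_component_table",
    "write_plink",
    "read_plink",
    "write_phenotype_file",
]

_FLOAT_FMT = "%.10g"


def write_tsv(path, df: pd.DataFrame, meta: Optional[Dict[str, str]] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    path.write_text(buf.getvalue())


def read_tsv(path) -> Tuple[pd.DataFrame, Dict[str, str]]:
    path = Path(path)
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


# ---------------------------------------------------------------- panel TSV

def write_panel_tsv(panel: GenotypePanel, prefix, meta=None) -> None:
    """``<prefix>.dosages.tsv`` (IID + one column per SNP) and
    ``<prefix>.snps.tsv`` (the SNP map)."""
    prefix = str(prefix)
    dos = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    dos.insert(0, "IID", panel.individual_ids)
    write_tsv(prefix + ".dosages.tsv", dos, meta)
    snps = pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "CHR": panel.chrom,
            "BP": panel.bp,
            "A1": panel.a1,
            "A2": panel.a2,
            "FREQ": panel.freq,
            "LD_BLOCK": -1 if panel.ld_block is None else panel.ld_block,
            "LD_COPY_PROB": panel.ld_copy_prob,
        }
    )
    write_tsv(prefix + ".snps.tsv", snps, meta)


def read_panel_tsv(prefix) -> GenotypePanel:
    prefix = str(prefix)
    dos, _ = read_tsv(prefix + ".dosages.tsv")
    snps, _ = read_tsv(prefix + ".snps.tsv")
    iid = dos.pop("IID").to_numpy(dtype=str)
    ld_block = snps["LD_BLOCK"].to_numpy()
    return GenotypePanel(
        dosages=dos.to_numpy(dtype=np.int8),
        snp_ids=snps["SNP"].to_numpy(dtype=str),
        chrom=snps["CHR"].to_numpy(dtype=np.int64),
        bp=snps["BP"].to_numpy(dtype=np.int64),
        a1=snps["A1"].to_numpy(dtype=str),
        a2=snps["A2"].to_numpy(dtype=str),
        freq=snps["FREQ"].to_numpy(dtype=np.float64),
        individual_ids=iid,
        ld_block=None if (ld_block < 0).all() else ld_block,
        ld_copy_prob=float(snps["LD_COPY_PROB"].iloc[0]),
    )


# ------------------------------------------------------------ components TSV

def write_component_table(table: ComponentTable, path, meta=None) -> None:
    df = table.values.copy()
    df.insert(0, "IID", table.individual_ids)
    df["excluded"] = table.excluded.astype(int)
    out = df.copy()
    for c in INTERNAL_TRAITS:
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    write_tsv(path, out, meta)


def read_component_table(path) -> ComponentTable:
    df, _ = read_tsv(path)
    vals = df[list(INTERNAL_TRAITS)].apply(pd.to_numeric, errors="coerce")
    return ComponentTable(
        individual_ids=df["IID"].to_numpy(dtype=str),
        values=vals.astype(np.float64),
        excluded=df["excluded"].to_numpy(dtype=bool),
    )


# ------------------------------------------------------------- PLINK binary

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit code -> dosage of the A1 allele (01 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write bed/bim/fam. Dosages count the bim A1 allele."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n, panel.m
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty((m, n), dtype=np.uint8)
        for d, c in _DOSAGE_TO_CODE.items():
            codes[panel.dosages.T == d] = c
        n_bytes = (n + 3) // 4
        packed = np.zeros((m, n_bytes), dtype=np.uint8)
        for i in range(n):
            packed[:, i // 4] |= codes[:, i] << (2 * (i % 4))
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "snp": panel.snp_ids,
            "cm": 0,
            "bp": panel.bp,
            "a1": panel.a1,
            "a2": panel.a2,
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False, lineterminator="\n")
    fam = pd.DataFrame(
        {
            "fid": panel.individual_ids,
            "iid": panel.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False, lineterminator="\n")


def read_plink(prefix) -> GenotypePanel:
    prefix = str(prefix)
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T
    if (dosages < 0).any():
        raise ValueError("missing genotypes are not supported by this panel format")
    freq = dosages.mean(axis=0) / 2.0
    return GenotypePanel(
        dosages=dosages.astype(np.int8),
        snp_ids=bim["snp"].to_numpy(dtype=str),
        chrom=bim["chrom"].to_numpy(dtype=np.int64),
        bp=bim["bp"].to_numpy(dtype=np.int64),
        a1=bim["a1"].to_numpy(dtype=str),
        a2=bim["a2"].to_numpy(dtype=str),
        freq=freq,
        individual_ids=fam["iid"].to_numpy(dtype=str),
    )


# -------------------------------------------------------- phenotype exports

def write_phenotype_file(assignment, individual_ids, path, meta=None) -> None:
    """PLINK-style phenotype TSV: 1 = control, 2 = case, NA otherwise."""
    status = assignment.status
    coded = np.where(
        status == CASE, "2", np.where(status == CONTROL, "1", "NA")
    )
    df = pd.DataFrame({"FID": individual_ids, "IID": individual_ids, "status": coded})
    write_tsv(path, df, meta)
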