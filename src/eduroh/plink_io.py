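"""PLINK 1 text (.ped/.map) and binary (.bed/.bim/.fam) genotype I/O.

Calls count copies of allele ``a1`` from the SNP map (2 = homozygous a1,
0 = homozygous a2, -1 = missing).  The binary format follows the PLINK 1
layout: magic bytes 0x6c 0x1b, SNP-major flag 0x01, then per SNP one
2-bit code per sample packed four to a byte, least significant pair
first (00 = hom a1, 01 = missing, 10 = het, 11 = hom a2).

The text reader assigns ``a1`` per SNP as the alphabetically first
observed allele, so text round-trips are faithful whenever the map's a1
sorts before a2 (as in the synthetic maps, which use A/B).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "read_plink",
    "read_plink_text",
    "read_plink_binary",
    "write_plink_text",
    "write_plink_binary",
    "write_covariates_tsv",
    "write_truth_bed",
]

_MAGIC = bytes([0x6C, 0x1B])

# byte value -> 4 calls (counted-a1 coding), LSB pair first
_DECODE = np.empty((256, 4), dtype=np.int8)
for _byte in range(256):
    for _k in range(4):
        code = (_byte >> (2 * _k)) & 0b11
        _DECODE[_byte, _k] = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}[code]
_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam if present, else ``prefix``.ped/.map."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_plink_binary(prefix)
    return read_plink_text(prefix)


# ---------------------------------------------------------------------------
# text format


def write_plink_text(G: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    sm = G.snp_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in sm.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")
    a1 = sm["a1"].to_numpy()
    a2 = sm["a2"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            calls = G.calls[i]
            for j in range(G.n_snps):
                c = calls[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 2:
                    fields += [a1[j], a1[j]]
                elif c == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink_text(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str},
    )
    rows = []
    sample_ids = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snp_map):
                raise ValueError(
                    f".ped line has {len(parts)} fields; expected "
                    f"{6 + 2 * len(snp_map)} for {len(snp_map)} SNPs"
                )
            sample_ids.append(parts[1])
            rows.append(parts[6:])
    alle = np.array(rows, dtype="U4").reshape(len(rows), len(snp_map), 2)
    n, m = alle.shape[0], alle.shape[1]
    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    for j in range(m):
        col = alle[:, j, :]
        seen = sorted(set(col.ravel()) - {"0"})
        if len(seen) > 2:
            raise ValueError(f"SNP {snp_map['snp'][j]} has >2 alleles: {seen}")
        a1 = seen[0] if seen else "A"
        a2 = seen[1] if len(seen) > 1 else ("B" if a1 != "B" else "A")
        a1s.append(a1)
        a2s.append(a2)
        valid = (col != "0").all(axis=1)
        calls[valid, j] = (col[valid] == a1).sum(axis=1)
    snp_map = snp_map.drop(columns=["cm"]).assign(a1=a1s, a2=a2s)
    return GenotypeMatrix(calls=calls, snp_map=snp_map, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# binary format


def write_plink_binary(G: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    sm = G.snp_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in sm.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\t{row['a1']}\t{row['a2']}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    n = G.n_samples
    n_bytes = (n + 3) // 4
    codes = np.zeros((G.n_snps, n_bytes * 4), dtype=np.uint8)
    for val, code in _ENCODE.items():
        codes[:, :n][G.calls.T == val] = code
    shifts = np.tile([0, 2, 4, 6], n_bytes)
    packed = (codes << shifts).reshape(G.n_snps, n_bytes, 4).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + b"\x01")
        fh.write(packed.tobytes())


def read_plink_binary(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    ).drop(columns=["cm"])
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str
    )
    sample_ids = fam[1].tolist()
    n = len(sample_ids)
    m = len(snp_map)
    n_bytes = (n + 3) // 4
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes; not a PLINK 1 .bed file")
    if raw[2] == 0x00:
        raise ValueError(f"{prefix}.bed is sample-major; only SNP-major is supported")
    if raw[2] != 0x01:
        raise ValueError(f"{prefix}.bed: unknown orientation byte {raw[2]:#x}")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * n_bytes:
        raise ValueError(
            f"{prefix}.bed is truncated or oversized: {body.size} data bytes, "
            f"expected {m * n_bytes}"
        )
    calls = _DECODE[body.reshape(m, n_bytes)].reshape(m, n_bytes * 4)[:, :n]
    return GenotypeMatrix(calls=calls.T.copy(), snp_map=snp_map, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# covariates and truth tables


def write_covariates_tsv(families: pd.DataFrame, path) -> None:
    """Covariate TSV with the canonical column order."""
    cols = [
        "family_id",
        "father_ea",
        "mother_ea",
        "offspring_ea",
        "f_lat",
        "f_lon",
        "m_lat",
        "m_lon",
        "o_lat",
        "o_lon",
        "religion",
        "city",
    ]
    extra = [c for c in families.columns if c not in cols]
    families[cols + extra].to_csv(path, sep="\t", index=False)


def write_truth_bed(hbd_segments: pd.DataFrame, path) -> None:
    """True HBD segments as BED-like TSV (chrom, start, end, sample)."""
    hbd_segments[["chrom", "start", "end", "sample"]].to_csv(
        path, sep="\t", index=False, header=False
    )
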