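"""LD pruning, run-of-homozygosity calling and the F_roh statistic.

The ROH definition is the strict consecutive-SNP rule used with pruned
array data: a run of at least ``min_snps`` consecutive homozygous calls
with no heterozygote allowed, preceded by variance-inflation-factor (VIF)
pruning in sliding windows (window 50 SNPs, step 5, VIF threshold 2).
F_roh is the summed ROH length divided by the SNP-mappable autosomal
length (2.77e9 bp for the real genotyping array; synthetic cohorts use
the mapped length of their own SNP map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ROHSegment",
    "vif_prune",
    "call_rohs",
    "compute_froh",
    "mappable_length_bp",
]


@dataclass(frozen=True)
class ROHSegment:
    """A maximal homozygous run: 1-based inclusive first/last SNP positions."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        # PLINK KB convention: span between first and last SNP, not +1
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# VIF pruning


def _window_vifs(C: np.ndarray) -> np.ndarray:
    """VIF of each variable given the others, from their correlation matrix.

    Uses the inverse-correlation diagonal when the matrix is well
    conditioned, otherwise falls back to per-variable regression R^2 via
    least squares (exact collinearity then yields an infinite VIF).
    """
    k = C.shape[0]
    if k == 1:
        return np.ones(1)
    try:
        cond = np.linalg.cond(C)
    except np.linalg.LinAlgError:  # pragma: no cover - cond rarely fails
        cond = np.inf
    if cond < 1e10:
        return np.diag(np.linalg.inv(C))
    vifs = np.empty(k)
    for i in range(k):
        others = np.delete(np.arange(k), i)
        coef, *_ = np.linalg.lstsq(C[np.ix_(others, others)], C[others, i], rcond=None)
        r2 = float(C[others, i] @ coef)
        vifs[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    G: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    vif_threshold: float = 2.0,
) -> np.ndarray:
    """Greedy sliding-window VIF pruning; returns kept SNP indices (ordered).

    Within each window (per chromosome, advancing by ``step_snps``), the SNP
    with the largest VIF — computed from regressing its standardised
    genotype on the other surviving SNPs in the window — is removed until
    all VIFs fall below ``vif_threshold``.  Ties are broken by removing the
    SNP with the lower minor-allele frequency.  Monomorphic SNPs are
    dropped up front.
    """
    if not (window_snps > step_snps > 0):
        raise ValueError("require window_snps > step_snps > 0")
    if not vif_threshold > 1:
        raise ValueError("vif_threshold must exceed 1")

    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(col_mean, inds[1])
    col_sd = calls.std(axis=0)

    removed = np.zeros(G.n_snps, dtype=bool)
    mono = col_sd == 0
    if mono.any():
        logger.info("vif_prune: dropping %d monomorphic SNPs", int(mono.sum()))
        removed |= mono

    p_hat = col_mean / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    Z = np.zeros_like(calls)
    ok = ~mono
    Z[:, ok] = (calls[:, ok] - col_mean[ok]) / col_sd[ok]
    n = calls.shape[0]

    chrom = G.snp_map["chrom"].astype(str).to_numpy()
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        for start in range(0, len(cidx), step_snps):
            widx = cidx[start : start + window_snps]
            widx = widx[~removed[widx]]
            if widx.size < 2:
                continue
            Zw = Z[:, widx]
            C = (Zw.T @ Zw) / n
            alive = np.ones(widx.size, dtype=bool)
            while alive.sum() >= 2:
                sub = np.flatnonzero(alive)
                vifs = _window_vifs(C[np.ix_(sub, sub)])
                worst = np.max(vifs)
                if worst < vif_threshold:
                    break
                cand = sub[np.isclose(vifs, worst)]  # isclose(inf, inf) is True
                if cand.size > 1:  # tie: drop the rarer allele
                    cand = cand[np.argsort(maf[widx[cand]], kind="stable")[:1]]
                alive[cand[0]] = False
                removed[widx[cand[0]]] = True
            if start + window_snps >= len(cidx):
                break
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# ROH calling


def _runs_bool(mask: np.ndarray):
    """Start/end (inclusive) index pairs of True runs in a 1-D bool array."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_rohs(
    G: GenotypeMatrix, min_snps: int = 65, *, missing_breaks: bool = True
) -> list:
    """Call runs of >= ``min_snps`` consecutive homozygous SNPs per sample.

    A heterozygous call always terminates a run.  With ``missing_breaks``
    (default) a missing call terminates it as well — the conservative
    reading of the no-heterozygote rule; with ``missing_breaks=False``
    missing calls are skipped: they neither break the run nor count toward
    ``min_snps``, and a run still starts and ends at homozygous SNPs.
    """
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    segments: list[ROHSegment] = []
    chrom = G.snp_map["chrom"].astype(str).to_numpy()
    pos = G.snp_map["pos"].to_numpy()
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        sub = G.calls[:, cidx]
        cpos = pos[cidx]
        hom = (sub == 0) | (sub == 2)
        miss = sub == MISSING
        for si, sample_id in enumerate(G.sample_ids):
            ok = hom[si] if missing_breaks else (hom[si] | miss[si])
            for a, b in _runs_bool(ok):
                if not missing_breaks:
                    # trim missing calls at the run edges
                    while a <= b and miss[si, a]:
                        a += 1
                    while b >= a and miss[si, b]:
                        b -= 1
                n_hom = int(hom[si, a : b + 1].sum())
                if n_hom >= min_snps:
                    segments.append(
                        ROHSegment(
                            sample_id=sample_id,
                            chromosome=c,
                            start_bp=int(cpos[a]),
                            end_bp=int(cpos[b]),
                            n_snps=n_hom,
                        )
                    )
    return segments


def segments_to_frame(segments) -> pd.DataFrame:
    """BED-like table (chrom, start, end, sample, n_snps, length_bp)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chromosome,
                "start": s.start_bp,
                "end": s.end_bp,
                "sample": s.sample_id,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "sample", "n_snps", "length_bp"],
    )


# ---------------------------------------------------------------------------
# F_roh


def mappable_length_bp(snp_map: pd.DataFrame) -> int:
    """Sum over chromosomes of (last - first) mapped position."""
    spans = snp_map.groupby("chrom", sort=False)["pos"].agg(["min", "max"])
    return int((spans["max"] - spans["min"]).sum())


def compute_froh(
    segments, denominator_bp: float, sample_ids=None
) -> pd.DataFrame:
    """Per-sample F_roh = summed ROH length / ``denominator_bp``.

    ``sample_ids`` supplies the full cohort so samples without any ROH get
    F_roh = 0; by default only samples present in ``segments`` appear.
    Overlapping segments within a sample indicate a caller bug and are
    rejected.
    """
    if not denominator_bp > 0:
        raise ValueError("denominator_bp must be positive")
    by_sample: dict = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    for sid, segs in by_sample.items():
        by_chrom: dict = {}
        for s in segs:
            by_chrom.setdefault(s.chromosome, []).append((s.start_bp, s.end_bp))
        for c, spans in by_chrom.items():
            spans.sort()
            for (a1, b1), (a2, _) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(
                        f"overlapping ROH segments for sample {sid} on chromosome {c}"
                    )
    if sample_ids is None:
        sample_ids = sorted(by_sample)
    total = {
        sid: float(sum(s.length_bp for s in by_sample.get(sid, ()))) for sid in sample_ids
    }
    froh = pd.DataFrame(
        {
            "sample": list(sample_ids),
            "froh": [total[s] / denominator_bp for s in sample_ids],
            "denominator_bp": float(denominator_bp),
        }
    )
    if (froh["froh"] > 1).any():
        raise ValueError("F_roh exceeds 1; check the denominator")
    return froh
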