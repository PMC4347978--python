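"""Two-generation synthetic cohort with educational assortment and migration.

The generator emulates the statistical structure of a Dutch family cohort in
which educational attainment (EA, ordinal 1-4) drives migration and mate
choice, and parental birthplace proximity drives offspring autozygosity:

* spouse EA is assorted through a Gaussian copula discretised at the EA
  marginal thresholds, calibrated to a target Spearman correlation;
* parents' birthplaces sit on a regular grid of demes; the mother's
  birthplace is displaced from the father's by an exponential distance whose
  mean follows the spouses' EA-specific migration scales, and the offspring
  birthplace is displaced from a migration-weighted point between them;
* parental kinship decays with birthplace distance, phi = phi0*exp(-d/lambda),
  and offspring homozygous-by-descent (HBD) tracts are laid down as a
  two-state Markov process with stationary HBD fraction phi/2;
* allele frequencies follow logistic clines in latitude/longitude with
  finite-pool drift per deme; outside HBD tracts the offspring receives one
  allele from the father's deme pool and one from the mother's, so ancestry
  reflects parental origins rather than the offspring's own birthplace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .geo import EARTH_RADIUS_KM, pairwise_km
from .genotypes import GenotypeMatrix
from .reference_tables import EA_MARGINALS, MIGRATION_KM_BY_EA

KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0

#: Offspring displacement scale as a multiple of the father's EA-specific
#: migration scale; calibrated by simulation so that the mean father-offspring
#: birthplace distance per paternal EA level matches that scale.
_OFFSPRING_DISP_FACTOR = 0.74

__all__ = [
    "DemeMap",
    "SimulationTruth",
    "build_deme_map",
    "default_deme_map",
    "default_snp_map",
    "simulate_families",
    "simulate_genotypes",
    "simulate_mediation_cohort",
    "simulate_correlation_trend",
    "latent_corr_for_spearman",
]


# ---------------------------------------------------------------------------
# Deme grid


@dataclass
class DemeMap:
    """Regular grid of demes (candidate birthplaces) on the sphere."""

    latitude: np.ndarray
    longitude: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    spacing_km: float
    origin: tuple

    @property
    def n_demes(self) -> int:
        return self.latitude.size

    @property
    def deme_id(self) -> np.ndarray:
        return np.arange(self.n_demes)

    @property
    def bounding_box(self) -> tuple:
        """(lat_min, lat_max, lon_min, lon_max) of the grid."""
        return (
            float(self.latitude.min()),
            float(self.latitude.max()),
            float(self.longitude.min()),
            float(self.longitude.max()),
        )

    def nearest(self, lat, lon) -> np.ndarray:
        """Index of the nearest deme for each (lat, lon), planar approximation."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        cosref = np.cos(np.radians(self.origin[0]))
        dy = (lat[:, None] - self.latitude[None, :]) * KM_PER_DEG_LAT
        dx = (lon[:, None] - self.longitude[None, :]) * KM_PER_DEG_LAT * cosref
        return np.argmin(dy * dy + dx * dx, axis=1)


def build_deme_map(n_x: int, n_y: int, spacing_km: float, origin=(52.0, 5.0)) -> DemeMap:
    """Regular ``n_x`` x ``n_y`` grid of demes with the given spacing in km.

    Longitude steps are scaled by each row's own cos(latitude) so that
    east-west neighbours are ``spacing_km`` apart at every row.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError(f"grid dimensions must be >= 1, got ({n_x}, {n_y})")
    if not spacing_km > 0:
        raise ValueError(f"spacing_km must be positive, got {spacing_km}")
    lat0, lon0 = float(origin[0]), float(origin[1])
    iy, ix = np.meshgrid(np.arange(n_y), np.arange(n_x), indexing="ij")
    iy = iy.ravel()
    ix = ix.ravel()
    lat = lat0 + iy * spacing_km / KM_PER_DEG_LAT
    lon = lon0 + ix * spacing_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return DemeMap(
        latitude=lat,
        longitude=lon,
        grid_x=ix,
        grid_y=iy,
        spacing_km=float(spacing_km),
        origin=(lat0, lon0),
    )


def default_deme_map() -> DemeMap:
    """20 x 30 grid at 10 km spacing: a Netherlands-shaped study region
    (about 200 km east-west by 300 km north-south)."""
    return build_deme_map(20, 30, 10.0, origin=(51.0, 4.0))


# ---------------------------------------------------------------------------
# Gaussian-copula ordinal assortment


def _thresholds(marginals) -> np.ndarray:
    m = np.asarray(marginals, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("marginals must be a 1-D vector with >= 2 categories")
    if np.any(m < 0) or not np.isclose(m.sum(), 1.0, atol=1e-8):
        raise ValueError("marginals must be non-negative and sum to 1")
    return stats.norm.ppf(np.cumsum(m)[:-1])


def _cell_probs(r: float, thr: np.ndarray) -> np.ndarray:
    """kxk cell probabilities of the threshold-discretised bivariate normal."""
    pts = np.concatenate([[-np.inf], thr, [np.inf]])
    k1 = pts.size
    phi = stats.norm.cdf(pts)
    dist = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    big = np.zeros((k1, k1))
    for i in range(k1):
        for j in range(k1):
            if np.isneginf(pts[i]) or np.isneginf(pts[j]):
                big[i, j] = 0.0
            elif np.isposinf(pts[i]):
                big[i, j] = phi[j]
            elif np.isposinf(pts[j]):
                big[i, j] = phi[i]
            else:
                big[i, j] = dist.cdf([pts[i], pts[j]])
    probs = np.clip(np.diff(np.diff(big, axis=0), axis=1), 0.0, 1.0)
    return probs / probs.sum()


def _table_spearman(probs: np.ndarray) -> float:
    """Population grade (midrank) correlation of a discrete bivariate table."""
    px = probs.sum(axis=1)
    py = probs.sum(axis=0)
    gx = np.concatenate([[0.0], np.cumsum(px)])[:-1] + px / 2.0
    gy = np.concatenate([[0.0], np.cumsum(py)])[:-1] + py / 2.0
    mx = float(px @ gx)
    my = float(py @ gy)
    sx = np.sqrt(float(px @ (gx - mx) ** 2))
    sy = np.sqrt(float(py @ (gy - my) ** 2))
    cov = float(((gx - mx)[:, None] * (gy - my)[None, :] * probs).sum())
    return cov / (sx * sy)


def latent_corr_for_spearman(target_rho: float, marginals) -> float:
    """Latent normal correlation whose discretised Spearman equals ``target_rho``.

    The discretised Spearman correlation is a strictly increasing function of
    the latent correlation; the inverse is found by root bracketing.
    """
    if abs(target_rho) >= 1.0:
        raise ValueError(f"unreachable assortment target rho={target_rho}")
    if target_rho == 0.0:
        return 0.0
    thr = _thresholds(marginals)
    # maximum attainable |Spearman| for these marginals
    hi = _table_spearman(_cell_probs(0.999, thr))
    if abs(target_rho) >= hi:
        raise ValueError(
            f"target Spearman rho={target_rho} exceeds the maximum "
            f"{hi:.3f} attainable with these marginals"
        )

    def f(r):
        return _table_spearman(_cell_probs(r, thr)) - target_rho

    return brentq(f, -0.999, 0.999, xtol=1e-6)


# ---------------------------------------------------------------------------
# Family simulation


def _km_offset_to_deg(dy_km, dx_km, at_lat):
    dlat = dy_km / KM_PER_DEG_LAT
    dlon = dx_km / (KM_PER_DEG_LAT * np.cos(np.radians(at_lat)))
    return dlat, dlon


def _displace_within_box(rng, lat0, lon0, radius_km, box, max_tries=25):
    """Displace each point by its radius at a uniform angle, resampling the
    angle until the target lands inside the bounding box.

    Conditioning on the direction (not the distance) keeps the drawn
    displacement distance intact, so expected distances are not truncated at
    the study-region border.  Points whose radius cannot be accommodated in
    any direction are clipped to the box after ``max_tries`` redraws.
    """
    lat_min, lat_max, lon_min, lon_max = box
    n = lat0.size
    lat = np.empty(n)
    lon = np.empty(n)
    active = np.ones(n, dtype=bool)
    for _ in range(max_tries):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        theta = rng.uniform(0.0, 2.0 * np.pi, idx.size)
        dlat, dlon = _km_offset_to_deg(
            radius_km[idx] * np.sin(theta), radius_km[idx] * np.cos(theta), lat0[idx]
        )
        cand_lat = lat0[idx] + dlat
        cand_lon = lon0[idx] + dlon
        ok = (
            (cand_lat >= lat_min)
            & (cand_lat <= lat_max)
            & (cand_lon >= lon_min)
            & (cand_lon <= lon_max)
        )
        lat[idx[ok]] = cand_lat[ok]
        lon[idx[ok]] = cand_lon[ok]
        # keep the latest candidate for still-failing points (clipped below)
        lat[idx[~ok]] = cand_lat[~ok]
        lon[idx[~ok]] = cand_lon[~ok]
        active[idx[ok]] = False
    np.clip(lat, lat_min, lat_max, out=lat)
    np.clip(lon, lon_min, lon_max, out=lon)
    return lat, lon


def simulate_families(
    n_families: int,
    ea_marginals=EA_MARGINALS,
    assortment_rho: float = 0.66,
    migration_km_by_ea=tuple(MIGRATION_KM_BY_EA["father_own"]["mean"]),
    deme_map: DemeMap | None = None,
    religion_prob: float = 0.5,
    seed: int = 0,
    *,
    mother_migration_km_by_ea=None,
    parent_offspring_rho: float = 0.40,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate a two-generation cohort of ``n_families`` families.

    Returns a DataFrame with one row per family: EA levels (1-4) for father,
    mother and offspring; birthplace coordinates for all three; binary
    religion and city-size indicators; birth years.

    Father EA is drawn from ``ea_marginals``; mother EA from a Gaussian
    copula calibrated so the spouse-pair Spearman correlation matches
    ``assortment_rho``; offspring EA from a latent mid-parent blend
    calibrated to ``parent_offspring_rho``.  The father's birthplace is a
    uniform deme; the mother's is displaced by an exponential distance with
    mean equal to the average of the spouses' EA-specific migration scales
    and snapped to the nearest deme; the offspring birthplace is displaced
    from the migration-weighted point between the parents by an exponential
    kick at the father's EA-specific migration scale (a patrilocal
    settlement convention that pins the father-offspring distance to the
    paternal migration scale for every spouse-pair combination).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    migration = np.asarray(migration_km_by_ea, dtype=float)
    if migration.shape != (4,) or np.any(migration < 0):
        raise ValueError("migration_km_by_ea must be 4 non-negative means (km)")
    if mother_migration_km_by_ea is None:
        migration_m = migration
    else:
        migration_m = np.asarray(mother_migration_km_by_ea, dtype=float)
        if migration_m.shape != (4,) or np.any(migration_m < 0):
            raise ValueError("mother_migration_km_by_ea must be 4 non-negative means")
    if not 0.0 <= religion_prob <= 1.0:
        raise ValueError("religion_prob must be a probability")
    if deme_map is None:
        deme_map = default_deme_map()

    rng = np.random.default_rng(seed)
    thr = _thresholds(ea_marginals)

    # --- ordinal EA via Gaussian copula ------------------------------------
    r_lat = latent_corr_for_spearman(assortment_rho, ea_marginals)
    z_f = rng.standard_normal(n_families)
    z_m = r_lat * z_f + np.sqrt(1.0 - r_lat**2) * rng.standard_normal(n_families)
    father_ea = np.searchsorted(thr, z_f) + 1
    mother_ea = np.searchsorted(thr, z_m) + 1

    r_po = latent_corr_for_spearman(parent_offspring_rho, ea_marginals)
    a = r_po / np.sqrt((1.0 + r_lat) / 2.0)
    if abs(a) >= 1.0:
        raise ValueError(
            "parent_offspring_rho unreachable given the assortment strength"
        )
    z_o = a * (z_f + z_m) / np.sqrt(2.0 * (1.0 + r_lat)) + np.sqrt(
        1.0 - a**2
    ) * rng.standard_normal(n_families)
    offspring_ea = np.searchsorted(thr, z_o) + 1

    # --- birthplaces --------------------------------------------------------
    f_idx = rng.integers(0, deme_map.n_demes, n_families)
    f_lat = deme_map.latitude[f_idx]
    f_lon = deme_map.longitude[f_idx]

    mu_f = migration[father_ea - 1]
    mu_m = migration_m[mother_ea - 1]
    mbar = (mu_f + mu_m) / 2.0

    box = deme_map.bounding_box
    d = rng.exponential(np.where(mbar > 0, mbar, 1e-12))
    d = np.where(mbar > 0, d, 0.0)
    m_raw_lat, m_raw_lon = _displace_within_box(rng, f_lat, f_lon, d, box)
    m_idx = deme_map.nearest(m_raw_lat, m_raw_lon)
    m_lat = deme_map.latitude[m_idx]
    m_lon = deme_map.longitude[m_idx]

    # offspring: migration-weighted point between parents + exponential kick
    w = np.where(mu_f + mu_m > 0, mu_f / np.where(mu_f + mu_m > 0, mu_f + mu_m, 1.0), 0.5)
    base_lat = f_lat + w * (m_lat - f_lat)
    base_lon = f_lon + w * (m_lon - f_lon)
    eps_r = rng.exponential(np.where(mu_f > 0, _OFFSPRING_DISP_FACTOR * mu_f, 1e-12))
    eps_r = np.where(mu_f > 0, eps_r, 0.0)
    o_lat, o_lon = _displace_within_box(rng, base_lat, base_lon, eps_r, box)

    # --- remaining covariates ----------------------------------------------
    religion = (rng.random(n_families) < religion_prob).astype(np.int8)
    city = (rng.random(n_families) < 0.5).astype(np.int8)
    o_year = rng.integers(1950, 1991, n_families)
    f_year = o_year - rng.integers(25, 36, n_families)
    m_year = o_year - rng.integers(25, 36, n_families)

    out = pd.DataFrame(
        {
            "family_id": [f"F{i:05d}" for i in range(n_families)],
            "father_ea": father_ea.astype(np.int8),
            "mother_ea": mother_ea.astype(np.int8),
            "offspring_ea": offspring_ea.astype(np.int8),
            "f_lat": f_lat,
            "f_lon": f_lon,
            "m_lat": m_lat,
            "m_lon": m_lon,
            "o_lat": o_lat,
            "o_lon": o_lon,
            "religion": religion,
            "city": city,
            "father_birth_year": f_year,
            "mother_birth_year": m_year,
            "offspring_birth_year": o_year,
        }
    )
    if missing_rate:
        if not 0.0 <= missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        # survey-style missingness on parental EA and parental birthplaces
        for cols in (["father_ea"], ["mother_ea"], ["f_lat", "f_lon"], ["m_lat", "m_lon"]):
            hit = rng.random(n_families) < missing_rate
            for col in cols:
                out[col] = out[col].astype(float)
                out.loc[hit, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# Genotype simulation


def default_snp_map(
    n_chromosomes: int = 5,
    snps_per_chromosome: int = 2000,
    chromosome_length_bp: int = 30_000_000,
) -> pd.DataFrame:
    """Evenly spaced SNP map: desk-scale stand-in for a pruned array."""
    frames = []
    for c in range(1, n_chromosomes + 1):
        pos = np.linspace(
            chromosome_length_bp / snps_per_chromosome,
            chromosome_length_bp,
            snps_per_chromosome,
        ).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c),
                    "pos": pos,
                    "snp": [f"snp{c}_{i}" for i in range(snps_per_chromosome)],
                    "a1": "A",
                    "a2": "B",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulationTruth:
    """Generator-side truth for a simulated cohort."""

    kinship: np.ndarray  # per-family parental kinship phi
    parental_distance_km: np.ndarray
    hbd_segments: pd.DataFrame  # columns: sample, chrom, start, end
    chrom_lengths_bp: dict
    params: dict = field(default_factory=dict)

    def hbd_fraction(self, sample_ids) -> np.ndarray:
        """True HBD genome fraction per sample (0 for samples with no tract)."""
        total = float(sum(self.chrom_lengths_bp.values()))
        out = pd.Series(0.0, index=list(sample_ids))
        if len(self.hbd_segments):
            lengths = (
                (self.hbd_segments["end"] - self.hbd_segments["start"])
                .groupby(self.hbd_segments["sample"])
                .sum()
            )
            out.loc[lengths.index] = lengths / total
        return out.to_numpy()


def _hbd_segments_for_sample(rng, phi, chrom_lengths, mean_tract_bp):
    """Alternating-renewal two-state chain along each chromosome."""
    segs = []
    if phi <= 0:
        return segs
    pi_hbd = phi / 2.0
    mean_out = mean_tract_bp * (1.0 - pi_hbd) / pi_hbd
    for chrom, length in chrom_lengths.items():
        pos = 0.0
        state = rng.random() < pi_hbd
        while pos < length:
            seg_len = rng.exponential(mean_tract_bp if state else mean_out)
            if state:
                start = int(pos) + 1
                end = int(min(pos + seg_len, length))
                if end > start:
                    segs.append((chrom, start, end))
            pos += seg_len
            state = not state
    return segs


def simulate_genotypes(
    families: pd.DataFrame,
    snp_map: pd.DataFrame | None = None,
    kinship_kernel=(0.05, 20.0),
    cline_strength: float = 0.08,
    pool_size: int = 500,
    seed: int = 0,
    *,
    deme_map: DemeMap | None = None,
    mean_hbd_tract_morgan: float = 0.03,
    cm_per_mb: float = 1.0,
    chunk_size: int = 256,
):
    """Simulate offspring genotypes with spatial clines and HBD tracts.

    Parameters
    ----------
    families
        Output of :func:`simulate_families`.
    snp_map
        Physical map sorted by (chrom, pos); default :func:`default_snp_map`.
    kinship_kernel
        ``(phi0, lambda_km)``: parental kinship phi = phi0*exp(-d/lambda)
        for parental birthplace distance d.
    cline_strength
        Standard deviation of the per-SNP logit-frequency slope per degree
        of latitude/longitude (each SNP gets its own random slope per axis).
    pool_size
        Haplotype-pool size per deme; realised deme frequencies are binomial
        draws of 2*pool_size haplotypes around the cline frequency (drift).
    mean_hbd_tract_morgan, cm_per_mb
        Mean HBD tract length on the genetic map and the physical-genetic
        scaling used to convert it to bp.

    Returns
    -------
    (GenotypeMatrix, SimulationTruth)
    """
    phi0, lam = float(kinship_kernel[0]), float(kinship_kernel[1])
    if not 0.0 <= phi0 <= 1.0:
        raise ValueError("phi0 must lie in [0, 1]")
    if not lam > 0:
        raise ValueError("lambda_km must be positive")
    if snp_map is None:
        snp_map = default_snp_map()
    if len(snp_map) == 0:
        raise ValueError("SNP map is empty")
    key = snp_map[["chrom", "pos"]]
    grouped_ok = all(
        np.all(np.diff(g["pos"].to_numpy()) > 0)
        for _, g in key.groupby("chrom", sort=False)
    )
    if not grouped_ok:
        raise ValueError("snp_map must be sorted by position within chromosome")
    if deme_map is None:
        deme_map = default_deme_map()

    n = len(families)
    m = len(snp_map)
    ss = np.random.SeedSequence(seed)
    rng_freq, rng_seg, rng_call = (np.random.default_rng(s) for s in ss.spawn(3))

    # parental kinship from birthplace distance
    d_par = pairwise_km(
        families["f_lat"].to_numpy(),
        families["f_lon"].to_numpy(),
        families["m_lat"].to_numpy(),
        families["m_lon"].to_numpy(),
    )
    phi = phi0 * np.exp(-d_par / lam)

    # per-SNP cline model and per-deme realised frequencies
    lat_c = deme_map.latitude.mean()
    lon_c = deme_map.longitude.mean()
    p0 = rng_freq.uniform(0.1, 0.9, m)
    b_lat = rng_freq.normal(0.0, cline_strength, m)
    b_lon = rng_freq.normal(0.0, cline_strength, m)

    f_deme = deme_map.nearest(families["f_lat"].to_numpy(), families["f_lon"].to_numpy())
    m_deme = deme_map.nearest(families["m_lat"].to_numpy(), families["m_lon"].to_numpy())
    occupied = np.unique(np.concatenate([f_deme, m_deme]))
    remap = np.full(deme_map.n_demes, -1)
    remap[occupied] = np.arange(occupied.size)
    logits = (
        logit(p0)[None, :]
        + b_lat[None, :] * (deme_map.latitude[occupied, None] - lat_c)
        + b_lon[None, :] * (deme_map.longitude[occupied, None] - lon_c)
    )
    p_cline = expit(logits)
    n_hap = 2 * int(pool_size)
    freq = rng_freq.binomial(n_hap, p_cline) / n_hap  # (occupied demes, m)

    # HBD truth segments
    chrom_lengths = {
        str(c): int(g["pos"].max()) for c, g in snp_map.groupby("chrom", sort=False)
    }
    mean_tract_bp = mean_hbd_tract_morgan * 100.0 / cm_per_mb * 1e6
    sample_ids = families["family_id"].tolist()
    seg_records = []
    segs_by_sample = []
    for i in range(n):
        segs = _hbd_segments_for_sample(rng_seg, phi[i], chrom_lengths, mean_tract_bp)
        segs_by_sample.append(segs)
        for chrom, start, end in segs:
            seg_records.append((sample_ids[i], chrom, start, end))
    hbd_df = pd.DataFrame(seg_records, columns=["sample", "chrom", "start", "end"])

    # per-chromosome SNP index ranges (map is chromosome-blocked)
    chrom_arr = snp_map["chrom"].astype(str).to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    chrom_slices = {}
    for c in chrom_lengths:
        idx = np.flatnonzero(chrom_arr == c)
        chrom_slices[c] = (idx[0], idx[-1] + 1)

    calls = np.empty((n, m), dtype=np.int8)
    fi = remap[f_deme]
    mi = remap[m_deme]
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        qf = freq[fi[lo:hi]]
        qm = freq[mi[lo:hi]]
        block = (
            (rng_call.random(qf.shape) < qf).astype(np.int8)
            + (rng_call.random(qm.shape) < qm).astype(np.int8)
        )
        for i in range(lo, hi):
            segs = segs_by_sample[i]
            if not segs:
                continue
            qbar = (qf[i - lo] + qm[i - lo]) / 2.0
            for chrom, start, end in segs:
                c0, c1 = chrom_slices[chrom]
                j0 = c0 + np.searchsorted(pos_arr[c0:c1], start, side="left")
                j1 = c0 + np.searchsorted(pos_arr[c0:c1], end, side="right")
                if j1 > j0:
                    block[i - lo, j0:j1] = 2 * (
                        rng_call.random(j1 - j0) < qbar[j0:j1]
                    ).astype(np.int8)
        calls[lo:hi] = block

    gm = GenotypeMatrix(calls=calls, snp_map=snp_map.reset_index(drop=True), sample_ids=sample_ids)
    truth = SimulationTruth(
        kinship=phi,
        parental_distance_km=d_par,
        hbd_segments=hbd_df,
        chrom_lengths_bp=chrom_lengths,
        params={
            "phi0": phi0,
            "lambda_km": lam,
            "cline_strength": cline_strength,
            "pool_size": int(pool_size),
            "mean_hbd_tract_morgan": mean_hbd_tract_morgan,
            "cm_per_mb": cm_per_mb,
            "genome_morgans": sum(chrom_lengths.values()) * cm_per_mb / 1e6 / 100.0,
            "seed": seed,
        },
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Lightweight structural-equation generators for the statistical modules


def simulate_mediation_cohort(
    n: int,
    *,
    ea_marginals=EA_MARGINALS,
    alpha_km_per_level: float = 10.0,
    beta_per_km: float = -2e-5,
    direct_per_level: float = 0.0,
    dist_noise_km: float = 30.0,
    froh_intercept: float = 0.003,
    froh_noise: float = 0.002,
    religion_effect: float = 5e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """Covariate-level cohort following the EA -> distance -> F_roh path model.

    Draws (EA, parental birthplace distance, F_roh, three ancestry PCs,
    religion, city) directly from the structural equations, for fast
    calibration and power studies of the regression/mediation machinery:

        distance = alpha_km_per_level*(EA-1) + Exp(dist_noise_km)
        F_roh    = intercept + beta_per_km*distance
                   + direct_per_level*(EA-1) + religion_effect*religion + noise

    ``direct_per_level = 0`` gives a pure (fully mediated) indirect effect.
    """
    rng = np.random.default_rng(seed)
    thr = _thresholds(ea_marginals)
    ea = np.searchsorted(thr, rng.standard_normal(n)) + 1
    distance = alpha_km_per_level * (ea - 1) + rng.exponential(dist_noise_km, n)
    religion = (rng.random(n) < 0.5).astype(np.int8)
    city = (rng.random(n) < 0.5).astype(np.int8)
    pcs = rng.standard_normal((n, 3))
    froh = (
        froh_intercept
        + beta_per_km * distance
        + direct_per_level * (ea - 1)
        + religion_effect * religion
        + froh_noise * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "ea": ea.astype(np.int8),
            "distance_km": distance,
            "froh": froh,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "religion": religion,
            "city": city,
        }
    )


def simulate_correlation_trend(
    n_per_group: int,
    rho0: float = 0.7,
    rho1: float = -0.06,
    groups=(0, 1, 2, 3),
    *,
    coord_mean: float = 52.0,
    coord_sd: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group bivariate normal (PC score, coordinate) with rho_g = rho0 + g*rho1.

    Emulates the moderated PC-geography correlation structure: one EA group
    per value in ``groups``, all sharing means and variances, differing only
    in correlation.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for g in groups:
        rho = rho0 + g * rho1
        if not -1 < rho < 1:
            raise ValueError(f"rho for group {g} out of (-1, 1): {rho}")
        z = rng.standard_normal((n_per_group, 2))
        pc = z[:, 0]
        coord = coord_mean + coord_sd * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
        frames.append(pd.DataFrame({"pc": pc, "coordinate": coord, "group": g}))
    return pd.concat(frames, ignore_index=True)
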