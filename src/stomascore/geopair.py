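"""Ellipsoidal geodesic distances and greedy historical-modern sample pairing.

Distances use the Vincenty inverse solution on the WGS84 ellipsoid. Vincenty's
iteration can fail to converge for nearly antipodal points; those fall back to
Lambert's approximation on reduced latitudes (metre-level at continental
scales, within ~0.1% of the true geodesic near the antipode) and are flagged.

Pairing is the greedy sequential procedure used with herbarium collections:
iterate historical samples in a deterministic order, match each to the nearest
remaining modern sample, consume that modern sample, then drop pairs that are
too distant, time-inverted or excluded by declarative region rules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# WGS84
_A = 6378137.0
_F = 1 / 298.257223563
_B = _A * (1 - _F)


def _vincenty_m(lat1, lon1, lat2, lon2, max_iter=200, tol=1e-12) -> float | None:
    """Vincenty inverse distance in metres; None on non-convergence."""
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _F) * math.tan(phi1))
    U2 = math.atan((1 - _F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        if cos2_alpha == 0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha
        C = _F / 16 * cos2_alpha * (4 + _F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        return None

    u2 = cos2_alpha * (_A**2 - _B**2) / _B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _B * A * (sigma - delta_sigma)


def _lambert_m(lat1, lon1, lat2, lon2) -> float:
    """Lambert's approximation on reduced latitudes (antipodal-safe)."""
    b1 = math.atan((1 - _F) * math.tan(math.radians(lat1)))
    b2 = math.atan((1 - _F) * math.tan(math.radians(lat2)))
    dlon = math.radians(lon2 - lon1)
    # central angle on the auxiliary sphere (haversine, numerically stable)
    h = (
        math.sin((b2 - b1) / 2) ** 2
        + math.cos(b1) * math.cos(b2) * math.sin(dlon / 2) ** 2
    )
    sigma = 2 * math.asin(min(1.0, math.sqrt(h)))
    if sigma == 0:
        return 0.0
    P = (b1 + b2) / 2
    Q = (b2 - b1) / 2
    X = (sigma - math.sin(sigma)) * (math.sin(P) ** 2 * math.cos(Q) ** 2) / math.cos(
        sigma / 2
    ) ** 2
    Y = (sigma + math.sin(sigma)) * (math.cos(P) ** 2 * math.sin(Q) ** 2) / math.sin(
        sigma / 2
    ) ** 2
    return _A * (sigma - _F / 2 * (X + Y))


def geodesic_with_method(a: tuple[float, float], b: tuple[float, float]) -> tuple[float, str]:
    """Distance in km between (lat, lon) points plus the algorithm used."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    d = _vincenty_m(a[0], a[1], b[0], b[1])
    if d is not None:
        return d / 1000.0, "vincenty"
    logger.warning(
        "Vincenty failed to converge for %s -> %s; using Lambert approximation", a, b
    )
    return _lambert_m(a[0], a[1], b[0], b[1]) / 1000.0, "lambert"


def geodesic_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """WGS84 geodesic distance in km between (lat, lon) points."""
    return geodesic_with_method(a, b)[0]


# ---------------------------------------------------------------------------
# sample metadata and pairing


REQUIRED_SAMPLE_COLUMNS = ("sample_id", "epoch", "year", "lat", "lon")


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample metadata table and normalise region tags to sets."""
    for col in REQUIRED_SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValueError(f"sample table missing column {col!r}")
    bad_lat = ~samples["lat"].between(-90, 90)
    bad_lon = ~samples["lon"].between(-180, 180)
    bad_year = ~samples["year"].between(1500, 2100)
    if bad_lat.any() or bad_lon.any() or bad_year.any():
        raise ValueError("sample table contains out-of-range coordinates or years")
    out = samples.copy()
    if "region_tags" not in out.columns:
        out["region_tags"] = [set() for _ in range(len(out))]
    else:
        out["region_tags"] = [
            set(str(t).split(";")) - {"", "nan"} if not isinstance(t, (set, frozenset)) else set(t)
            for t in out["region_tags"]
        ]
    return out


def _rule_excludes_sample(sample, rules) -> bool:
    for rule in rules:
        kind = rule.get("kind")
        if kind == "exclude_tag" and rule["tag"] in sample.region_tags:
            return True
        if kind == "exclude_lon_west_of" and sample.lon < rule["lon"]:
            return True
    return False


def _rule_excludes_pair(hist, mod, rules) -> str | None:
    for rule in rules:
        if rule.get("kind") == "forbid_cross":
            tag = rule["tag"]
            if (tag in hist.region_tags) != (tag in mod.region_tags):
                return f"cross_{tag}"
        if rule.get("kind") == "forbid_mismatch":
            prefix = rule["prefix"]
            h = {t for t in hist.region_tags if t.startswith(prefix)}
            m = {t for t in mod.region_tags if t.startswith(prefix)}
            if h != m:
                return f"mismatch_{prefix}"
    return None


def pair_samples(
    samples: pd.DataFrame,
    max_km: float = 500.0,
    order_policy: str = "sample_id",
    seed: int | None = None,
    exclusion_rules: list[dict] | None = None,
) -> pd.DataFrame:
    """Greedy nearest-neighbour pairing of historical to modern samples.

    Historical samples are visited under ``order_policy`` ('sample_id',
    'year', or 'random' with ``seed``); each takes the geodesically nearest
    modern sample still in the pool, which is then consumed. The selected
    pair is afterwards dropped (with a recorded reason) if its distance
    exceeds ``max_km``, its year gap is not positive, or a declarative
    exclusion rule fires. Each modern sample appears in at most one pair.

    Returns a table with columns hist_id, mod_id, distance_km, year_gap,
    method, excluded_reason (empty string for kept pairs) and kept.
    """
    samples = validate_samples(samples)
    exclusion_rules = exclusion_rules or []
    hist = samples[samples["epoch"] == "historical"]
    mod = samples[samples["epoch"] == "modern"]
    if hist.empty or mod.empty:
        raise ValueError("pairing requires non-empty historical and modern sets")

    hist = hist[[not _rule_excludes_sample(s, exclusion_rules) for s in hist.itertuples()]]
    mod = mod[[not _rule_excludes_sample(s, exclusion_rules) for s in mod.itertuples()]]

    if order_policy == "sample_id":
        hist = hist.sort_values("sample_id")
    elif order_policy == "year":
        hist = hist.sort_values(["year", "sample_id"])
    elif order_policy == "random":
        rng = np.random.default_rng(seed)
        hist = hist.iloc[rng.permutation(len(hist))]
    else:
        raise ValueError(f"unknown order_policy {order_policy!r}")

    pool = list(mod.itertuples())
    rows = []
    for h in hist.itertuples():
        if not pool:
            rows.append(
                {
                    "hist_id": h.sample_id,
                    "mod_id": "",
                    "distance_km": float("nan"),
                    "year_gap": np.nan,
                    "method": "",
                    "excluded_reason": "modern_pool_exhausted",
                    "kept": False,
                }
            )
            continue
        dists = [geodesic_with_method((h.lat, h.lon), (m.lat, m.lon)) for m in pool]
        j = int(np.argmin([d for d, _ in dists]))
        m = pool.pop(j)
        dist_km, method = dists[j]
        year_gap = int(m.year - h.year)
        reason = ""
        if dist_km > max_km:
            reason = "distance"
        elif year_gap <= 0:
            reason = "year_gap"
        else:
            rule_reason = _rule_excludes_pair(h, m, exclusion_rules)
            if rule_reason:
                reason = rule_reason
        rows.append(
            {
                "hist_id": h.sample_id,
                "mod_id": m.sample_id,
                "distance_km": dist_km,
                "year_gap": year_gap,
                "method": method,
                "excluded_reason": reason,
                "kept": reason == "",
            }
        )
    result = pd.DataFrame(rows)
    n_kept = int(result["kept"].sum())
    logger.info(
        "pair_samples: %d/%d historical samples paired (policy=%s, max_km=%g)",
        n_kept,
        len(hist),
        order_policy,
        max_km,
    )
    return result
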