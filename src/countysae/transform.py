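"""Arcsine-square-root scale: variance-stabilizing transform and level-1 assembly.

``y = arcsin(sqrt(p))`` has sampling variance approximately ``1/(4 n)``
independent of ``p`` — the stabilization that lets the area-level model treat
the level-1 variances as known.  With complex-design weights ``n`` is
replaced by the effective sample size.

The level-1 observation vector per county has four components, in fixed
order: the three in-person-survey stratum estimates (landline, cell-only,
no phone) and the telephone-survey landline estimate.  A boolean mask marks
which components a county actually contributes (most counties have only the
telephone component).  The level-1 covariance is taken diagonal: stratum
estimates are independent given the stratum means, and the two surveys are
independent; this is the minimal assumption and is isolated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .direct import NATIONAL_ID
from .synthetic import STRATA

__all__ = [
    "COMPONENTS",
    "TransformedVector",
    "Level1Data",
    "to_arcsine",
    "from_arcsine",
    "assemble_level1",
]

#: Fixed component order of the level-1 vector.
COMPONENTS = ("nhis_landline", "nhis_cellonly", "nhis_nophone", "brfss")


def to_arcsine(p_hat, n_eff, n=None):
    """Transform a proportion to the arcsine-root scale.

    Returns ``(y, v)`` with ``y = arcsin(sqrt(p_hat))`` and ``v = 1/(4 n_eff)``.
    When ``n`` is given, boundary estimates (0 or 1) are first shrunk toward
    0.5 by ``1/(4n)`` (Anscombe-style guard) so the transform is not pinned
    at the edge of its range.
    """
    p = np.asarray(p_hat, dtype=float)
    ne = np.asarray(n_eff, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_hat must lie in [0, 1]")
    if np.any(ne <= 0):
        raise ValueError("n_eff must be positive")
    if n is not None:
        guard = 1.0 / (4.0 * np.asarray(n, dtype=float))
        p = np.clip(p, guard, 1.0 - guard)
    y = np.arcsin(np.sqrt(p))
    v = 1.0 / (4.0 * ne)
    if np.isscalar(p_hat):
        return float(y), float(v)
    return y, v


def from_arcsine(y):
    """Inverse map: p = sin^2(y) for y in [0, pi/2]."""
    arr = np.asarray(y, dtype=float)
    if np.any((arr < 0) | (arr > np.pi / 2)):
        raise ValueError("y must lie in [0, pi/2]")
    p = np.sin(arr) ** 2
    return float(p) if np.isscalar(y) else p


@dataclass
class TransformedVector:
    """Level-1 observation for one county: y, v and presence mask per component."""

    county_id: str
    y: np.ndarray
    v: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.shape != (4,) or self.v.shape != (4,) or self.mask.shape != (4,):
            raise ValueError("y, v, mask must each have 4 components")
        if not self.mask.any():
            raise ValueError("county contributes no component")
        obs = self.mask
        if np.any((self.y[obs] < 0) | (self.y[obs] > np.pi / 2)):
            raise ValueError("observed y outside [0, pi/2]")
        if np.any(self.v[obs] <= 0):
            raise ValueError("observed v must be positive")


@dataclass
class Level1Data:
    """Stacked level-1 observations for all retained counties."""

    county_ids: np.ndarray            # (m,) str
    y: np.ndarray                     # (m, 4)
    v: np.ndarray                     # (m, 4)
    mask: np.ndarray                  # (m, 4) bool
    excluded: list[tuple[str, str]]   # (county_id, reason)

    def __len__(self) -> int:
        return len(self.county_ids)

    def vectors(self) -> list[TransformedVector]:
        return [
            TransformedVector(cid, self.y[i], self.v[i], self.mask[i])
            for i, cid in enumerate(self.county_ids)
        ]

    def to_frame(self) -> pd.DataFrame:
        rec = []
        for i, cid in enumerate(self.county_ids):
            for k, comp in enumerate(COMPONENTS):
                rec.append({
                    "county_id": cid, "component": comp,
                    "y": self.y[i, k], "v": self.v[i, k],
                    "mask": int(self.mask[i, k]),
                })
        return pd.DataFrame(rec)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Level1Data":
        ids = np.array(sorted(df["county_id"].unique()))
        idx = {c: i for i, c in enumerate(ids)}
        comp = {c: k for k, c in enumerate(COMPONENTS)}
        m = len(ids)
        y = np.zeros((m, 4))
        v = np.full((m, 4), 1.0)
        mask = np.zeros((m, 4), dtype=bool)
        for _, r in df.iterrows():
            i, k = idx[r["county_id"]], comp[r["component"]]
            y[i, k], v[i, k], mask[i, k] = r["y"], r["v"], bool(r["mask"])
        return cls(ids, y, v, mask, [])


def assemble_level1(
    nhis_estimates: pd.DataFrame,
    brfss_estimates: pd.DataFrame,
    min_n: int = 2,
) -> Level1Data:
    """Build the per-county level-1 vectors from the two direct-estimate tables.

    Stratum estimates with fewer than ``min_n`` respondents are dropped
    (the point estimate exists but its variance is too unstable for level 1).
    A county absent from both surveys after filtering is excluded with a
    recorded reason.  ``v`` is ``1/(4 n_eff)`` per component.
    """
    nhis = nhis_estimates[nhis_estimates["county_id"] != NATIONAL_ID]
    brfss = brfss_estimates[brfss_estimates["county_id"] != NATIONAL_ID]

    all_ids = sorted(set(nhis["county_id"]) | set(brfss["county_id"]))
    comp_of_stratum = {s: k for k, s in enumerate(STRATA)}

    y = {}
    v = {}
    mask = {}
    for cid in all_ids:
        y[cid] = np.zeros(4)
        v[cid] = np.ones(4)
        mask[cid] = np.zeros(4, dtype=bool)

    for _, r in nhis.iterrows():
        if r["stratum"] == "all" or r["n"] < min_n:
            continue
        k = comp_of_stratum[r["stratum"]]
        yy, vv = to_arcsine(r["p_hat"], r["n_eff"], n=r["n"])
        cid = r["county_id"]
        y[cid][k], v[cid][k], mask[cid][k] = yy, vv, True

    for _, r in brfss.iterrows():
        if r["stratum"] != "landline" or r["n"] < min_n:
            continue
        yy, vv = to_arcsine(r["p_hat"], r["n_eff"], n=r["n"])
        cid = r["county_id"]
        y[cid][3], v[cid][3], mask[cid][3] = yy, vv, True

    kept, excluded = [], []
    for cid in all_ids:
        if mask[cid].any():
            kept.append(cid)
        else:
            excluded.append((cid, f"no stratum with n >= {min_n} in either survey"))

    return Level1Data(
        county_ids=np.array(kept),
        y=np.array([y[c] for c in kept]),
        v=np.array([v[c] for c in kept]),
        mask=np.array([mask[c] for c in kept]),
        excluded=excluded,
    )
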