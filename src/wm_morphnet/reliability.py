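"""Edgewise test-retest reliability and twin-based heritability.

Reliability is the one-way random-effects intraclass correlation

    ICC = (MS_b - MS_w) / (MS_b + (k - 1) MS_w)

computed per edge from a balanced subjects x sessions panel, banded into the
conventional poor/low/fair/good/excellent categories. Heritability follows
the ACE decomposition of phenotypic variance into additive-genetic (A),
common-environment (C) and unique-environment (E) components, estimated per
edge by the Falconer method of moments from monozygotic (MZ) and dizygotic
(DZ) intrapair correlations, with h^2 = A / (A + C + E) and significance by
permutation of the pairs' zygosity labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .inference import fdr_bh

__all__ = [
    "SessionPanel",
    "TwinPanel",
    "icc",
    "classify_icc",
    "falconer_ace",
    "ace_heritability",
    "HeritabilityResult",
]


@dataclass
class SessionPanel:
    """Balanced multi-session edge values: subjects x sessions x edges."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be subjects x sessions x edges")
        n, k, _ = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if k < 2:
            raise ValueError("need at least 2 sessions per subject (balanced)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel values must be finite (balanced design)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def n_edges(self) -> int:
        return self.values.shape[2]


@dataclass
class TwinPanel:
    """Twin-pair edge values: pairs x 2 members x edges, with zygosity."""

    values: np.ndarray
    zygosity: np.ndarray  # 'MZ' or 'DZ' per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must be pairs x 2 x edges")
        self.zygosity = np.asarray(self.zygosity)
        if self.zygosity.shape != (self.values.shape[0],):
            raise ValueError("one zygosity label per pair required")
        bad = set(np.unique(self.zygosity)) - {"MZ", "DZ"}
        if bad:
            raise ValueError(f"zygosity labels must be MZ/DZ, got {sorted(bad)}")
        if (self.zygosity == "MZ").sum() < 2 or (self.zygosity == "DZ").sum() < 2:
            raise ValueError("need at least 2 MZ and 2 DZ pairs")

    @property
    def n_edges(self) -> int:
        return self.values.shape[2]


def icc(panel: SessionPanel) -> np.ndarray:
    """One-way random-effects ICC per edge; may be negative.

    MS_b is the between-subject mean square, MS_w the within-subject mean
    square of a balanced one-way ANOVA with k repeated sessions.
    """
    x = panel.values  # n x k x E
    n, k, _ = x.shape
    subj_means = x.mean(axis=1)  # n x E
    grand = subj_means.mean(axis=0)  # E
    ms_b = k * ((subj_means - grand) ** 2).sum(axis=0) / (n - 1)
    ms_w = ((x - subj_means[:, None, :]) ** 2).sum(axis=(0, 1)) / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (ms_b - ms_w) / denom
    return out


_ICC_BANDS = [
    (0.25, "poor"),
    (0.4, "low"),
    (0.6, "fair"),
    (0.75, "good"),
    (np.inf, "excellent"),
]


def classify_icc(value: float) -> str:
    """Reliability category: poor < 0.25 <= low < 0.4 <= fair < 0.6 <= good
    < 0.75 <= excellent."""
    for bound, name in _ICC_BANDS:
        if value < bound:
            return name
    return "excellent"


def _pair_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation between member-1 and member-2 values."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def falconer_ace(r_mz: np.ndarray, r_dz: np.ndarray) -> np.ndarray:
    """Heritability h^2 from intrapair correlations by the Falconer method.

    A = 2 (r_MZ - r_DZ), C = 2 r_DZ - r_MZ, E = 1 - r_MZ; components are
    projected onto the nonnegative orthant before h^2 = A / (A + C + E), so
    h^2 always lies in [0, 1].
    """
    r_mz = np.asarray(r_mz, dtype=float)
    r_dz = np.asarray(r_dz, dtype=float)
    a = np.clip(2.0 * (r_mz - r_dz), 0.0, None)
    c = np.clip(2.0 * r_dz - r_mz, 0.0, None)
    e = np.clip(1.0 - r_mz, 0.0, None)
    total = a + c + e
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(total > 0, a / np.where(total > 0, total, 1.0), 0.0)
    h2 = np.where(np.isnan(r_mz) | np.isnan(r_dz), np.nan, h2)
    return h2


def _h2_for_labels(
    values: np.ndarray, is_mz: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Projected h^2 and the unprojected additive estimate 2(r_MZ - r_DZ)."""
    r_mz = _pair_correlations(values[is_mz, 0], values[is_mz, 1])
    r_dz = _pair_correlations(values[~is_mz, 0], values[~is_mz, 1])
    return falconer_ace(r_mz, r_dz), 2.0 * (r_mz - r_dz)


@dataclass
class HeritabilityResult:
    h2: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    excluded: np.ndarray  # zero-variance edges (h2 undefined)


def ace_heritability(
    panel: TwinPanel,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    q: float = 0.05,
) -> HeritabilityResult:
    """Per-edge heritability with zygosity-permutation significance.

    The permutation null shuffles the MZ/DZ labels across pairs while keeping
    each pair intact; p uses the add-one rule
    p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm) on the *unprojected*
    additive estimate 2 (r_MZ - r_DZ), whose null distribution is continuous
    (the projected h^2 sits exactly at 0 for half the null edges, which would
    make the permutation p conservative and badly calibrated). The FDR mask
    is the Benjamini-Hochberg step-up at level ``q`` over the defined edges.
    """
    values = panel.values
    is_mz = panel.zygosity == "MZ"
    var = values.reshape(-1, panel.n_edges).var(axis=0)
    excluded = var == 0
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} zero-variance edge(s) excluded from heritability"
        )
    h2, a_obs = _h2_for_labels(values, is_mz)
    h2[excluded] = np.nan
    rng = np.random.default_rng(seed)
    exceed = np.zeros(panel.n_edges)
    labels = is_mz.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        _, a_perm = _h2_for_labels(values, labels)
        exceed += np.where(np.isnan(a_perm), 0.0, a_perm >= a_obs)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[excluded | np.isnan(h2)] = np.nan
    mask = np.zeros(panel.n_edges, dtype=bool)
    defined = ~np.isnan(p)
    if defined.any():
        mask[defined] = fdr_bh(p[defined], q=q)
    return HeritabilityResult(h2=h2, p=p, fdr_mask=mask, excluded=excluded)
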