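"""Hydrogen-isotope fractionation between leaf waxes and plant source water.

The isotopic enrichment of a wax compound relative to its source water is

    eps = ((dD_wax + 1000) / (dD_source + 1000) - 1) * 1000        [permil]

where dD values are per mil vs VSMOW.  The source is either measured xylem
water or, where stems could not be sampled (ferns and lycopods with green,
photosynthetic stems), the mean environmental (precipitation) water.  Also
provided: abundance-weighted average chain length (ACL) and the total
acid:alkane mass ratio used to summarize wax composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import CANONICAL_COMPOUNDS, CompoundSpec

XYLEM = "xylem"
ENVIRON = "environ"

_DD_RANGE = (-500.0, 100.0)


class MissingSourceWaterError(ValueError):
    """Neither xylem nor environmental water is available for a sample."""


def compute_epsilon(dD_wax: float, dD_source: float) -> float:
    """Fractionation (permil) of a wax compound relative to its source water.

    Both arguments are per-mil delta values; the computation converts to
    isotope-ratio space via the +1000 offset.
    """
    if dD_source <= -1000.0:
        raise ValueError(
            f"source water dD = {dD_source} permil implies a non-positive "
            "isotope ratio"
        )
    return ((dD_wax + 1000.0) / (dD_source + 1000.0) - 1.0) * 1000.0


def resolve_source(sample: "SpeciesSample", prefer: str = XYLEM) -> tuple[float, bool]:
    """Pick the source-water dD for a sample.

    Returns ``(dD_source, fallback)`` where ``fallback`` is True when xylem
    water was requested but absent and environmental water was substituted.
    """
    if prefer == ENVIRON:
        return sample.dD_environ, False
    if prefer != XYLEM:
        raise ValueError(f"prefer must be 'xylem' or 'environ', got {prefer!r}")
    if sample.dD_xylem is not None:
        return sample.dD_xylem, False
    if sample.dD_environ is None:
        raise MissingSourceWaterError(
            f"sample {sample.species!r} has neither xylem nor environmental water"
        )
    return sample.dD_environ, True


@dataclass
class SpeciesSample:
    """One plant's measured dD values plus its classification labels."""

    species: str
    dD_wax: dict[str, float]  # compound id -> permil; missing keys allowed
    dD_environ: float
    dD_xylem: float | None = None
    dD_leafwater: float | None = None
    lineage: str | None = None
    growth_form: str | None = None
    pathway: str | None = None

    def __post_init__(self) -> None:
        if not self.dD_wax:
            raise ValueError(f"sample {self.species!r} has no wax measurements")
        lo, hi = _DD_RANGE
        for name, v in [("dD_environ", self.dD_environ),
                        ("dD_xylem", self.dD_xylem),
                        ("dD_leafwater", self.dD_leafwater),
                        *[(k, v) for k, v in self.dD_wax.items()]]:
            if v is not None and not (lo < v < hi):
                raise ValueError(
                    f"sample {self.species!r}: {name} = {v} permil outside "
                    f"plausible range ({lo}, {hi})"
                )


@dataclass
class FractionationMatrix:
    """Species x compound grid of fractionation values (permil).

    ``values`` is a DataFrame indexed by species with one column per
    compound id; NaN marks a missing measurement.  ``fallback_species``
    records which rows used environmental water in place of xylem water.
    """

    values: pd.DataFrame
    source_kind: str
    fallback_species: tuple[str, ...] = ()
    labels: pd.DataFrame | None = None

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.columns)


def build_fractionation_matrix(
    samples: list[SpeciesSample],
    prefer: str = XYLEM,
    compounds: tuple[CompoundSpec, ...] = CANONICAL_COMPOUNDS,
) -> FractionationMatrix:
    """Per-compound fractionation for every sample against one source kind.

    Missing wax measurements propagate as NaN; they are never zero-filled.
    """
    if not samples:
        raise ValueError("no samples provided")
    cols = [c.id for c in compounds]
    rows = np.full((len(samples), len(cols)), np.nan)
    fallbacks: list[str] = []
    label_rows = []
    for i, s in enumerate(samples):
        src, fb = resolve_source(s, prefer)
        if fb:
            fallbacks.append(s.species)
        for j, cid in enumerate(cols):
            v = s.dD_wax.get(cid)
            if v is not None and not np.isnan(v):
                rows[i, j] = compute_epsilon(v, src)
        label_rows.append((s.lineage, s.growth_form, s.pathway))
    values = pd.DataFrame(rows, index=[s.species for s in samples], columns=cols)
    labels = pd.DataFrame(
        label_rows,
        index=values.index,
        columns=["lineage", "growth_form", "pathway"],
    )
    kind = XYLEM if prefer == XYLEM else ENVIRON
    return FractionationMatrix(
        values=values, source_kind=kind,
        fallback_species=tuple(fallbacks), labels=labels,
    )


@dataclass
class LipidAbundanceProfile:
    """Per-compound abundances (ug per g dry leaf) with ACL and acid:alkane R."""

    abundances: dict[str, float]
    acl_acid: float | None = None
    acl_alkane: float | None = None
    ratio: float | None = None


def compute_acl(abundances: np.ndarray, chain_lengths: np.ndarray) -> float:
    """Abundance-weighted mean carbon number of a homolog series."""
    abundances = np.asarray(abundances, dtype=float)
    chain_lengths = np.asarray(chain_lengths, dtype=float)
    if np.any(abundances < 0):
        raise ValueError("abundances must be non-negative")
    total = abundances.sum()
    if total <= 0:
        raise ValueError("total abundance is zero; ACL undefined")
    return float((abundances * chain_lengths).sum() / total)


def acid_alkane_ratio(acid_abundances: np.ndarray, alkane_abundances: np.ndarray) -> float:
    """Ratio of total n-acid mass to total n-alkane mass."""
    acid_total = float(np.asarray(acid_abundances, dtype=float).sum())
    alkane_total = float(np.asarray(alkane_abundances, dtype=float).sum())
    if alkane_total <= 0:
        raise ValueError("total alkane abundance is zero; ratio undefined")
    return acid_total / alkane_total
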