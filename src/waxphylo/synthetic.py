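"""Synthetic botanical-garden studies with known generating truth.

Emulates the structure of a common-garden leaf-wax isotope survey:
~100 vascular-plant species on an ultrametric phylogeny, partitioned into
eight nested lineage classes, with a latent integrated fractionation
trait evolving under a three-optimum Ornstein-Uhlenbeck process (distinct
optima for the BEP grass clade, the remaining monocots, and all other
plants).  Each of the seven wax compounds reports the latent trait
through its own affine map plus noise, which reproduces the observed
correlated-but-offset compound series (pairwise R-squared around
0.7-0.9, non-unit slopes, nonzero intercepts).  Wax delta-D values are
back-computed by inverting the fractionation equation against simulated
xylem water (mean -57 permil, the mean-annual-precipitation value used
as environmental water), so the fractionation stage of the pipeline is
exercised as the exact inverse of the generator.  Growth form is
confounded with lineage by construction: the graminoid form occurs only
inside the Poales-analog clade, while other forms are assigned
independently of the tree.  C4 labels occur only on non-BEP grass
analogs and shift fractionation toward less negative values.

One global seed expands into independent per-stage streams (tree,
structure, trait, compounds, water, missingness) via numpy
``SeedSequence(seed, spawn_key=(stage,))``, so each stage is
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compounds import ACIDS, ALKANES, CANONICAL_COMPOUNDS
from .comparative import Phylogeny, RegimePainting, paint_regimes, simulate_ou
from .fractionation import SpeciesSample

_STAGES = {"tree": 0, "structure": 1, "trait": 2, "compounds": 3,
           "water": 4, "missing": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage generator derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    )


@dataclass
class CompoundChannel:
    """Affine read-out of the latent trait for one compound:
    eps_c = intercept + slope * latent + Normal(0, noise_sd), in permil."""

    intercept: float
    slope: float
    noise_sd: float


def _default_channels() -> dict[str, CompoundChannel]:
    # intercepts put raw fractionation in the -100..-180 permil range
    # typical of leaf waxes; slopes differ from 1 and intercepts from 0 so
    # inter-compound regressions are correlated but not 1:1.
    spec = {
        "C24_acid": (-118.0, 1.00, 9.0),
        "C26_acid": (-124.0, 0.92, 9.5),
        "C28_acid": (-120.0, 1.05, 8.5),
        "C30_acid": (-131.0, 0.88, 10.0),
        "C27_alkane": (-127.0, 1.10, 9.0),
        "C29_alkane": (-122.0, 1.00, 8.5),
        "C31_alkane": (-134.0, 0.85, 10.5),
    }
    return {k: CompoundChannel(*v) for k, v in spec.items()}


@dataclass
class SyntheticConfig:
    """Generating parameters of a synthetic study.

    Defaults follow the emulated study design: 100 species, a three-regime
    OU truth with optima (16.31, -27.82, -56.44) in integrated scaled
    units, xylem water near -57 permil, and a +20 permil C4 shift
    (C4 grasses fractionate ~20 permil less, in absolute value, than C3
    grasses).
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    unit_branch_lengths: bool = False
    # nested clade fractions of n_tips
    monocot_fraction: float = 0.30
    poales_fraction: float = 0.20
    bep_fraction: float = 0.12
    # OU truth; regime order: 0 = non-monocot, 1 = non-BEP monocot, 2 = BEP
    alpha: float = 2.0
    sigma2: float = 200.0
    theta: tuple[float, float, float] = (16.31, -27.82, -56.44)
    # compound read-out channels
    channels: dict[str, CompoundChannel] = field(default_factory=_default_channels)
    # per-species compound-class factor (permil sd): +u on acids, -u on
    # alkanes, emulating class-specific biosynthetic offsets that put acids
    # and alkanes on opposite sides of the second principal component
    class_factor_sd: float = 5.0
    # water model (permil)
    xylem_mean: float = -57.0
    xylem_sd: float = 3.0
    environ: float = -57.0
    leafwater_evap_offset: float = 15.0
    graminoid_leafwater_extra: float = 12.0
    # pathway shifts on per-compound fractionation (permil)
    c4_offset: float = 20.0
    cam_offset: float = 10.0
    n_c4: int = 4
    n_cam: int = 3
    # fraction of wax cells dropped at random
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("monocot_fraction", "poales_fraction", "bep_fraction"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.bep_fraction < self.poales_fraction < self.monocot_fraction:
            raise ValueError("clade fractions must nest: bep < poales < monocot")
        if self.xylem_sd < 0 or self.missing_rate < 0:
            raise ValueError("sds and rates must be >= 0")


@dataclass
class SyntheticDataset:
    """A complete simulated study plus its generating truth."""

    samples: list[SpeciesSample]
    table: pd.DataFrame
    tree: Phylogeny
    painting: RegimePainting
    labels: pd.DataFrame            # species x (lineage, growth_form, pathway)
    latent: pd.Series               # true integrated trait per tip
    epsilon_true: pd.DataFrame      # noiseless-source per-compound eps (permil)
    config: SyntheticConfig
    clades: dict[str, int]          # named clade root nodes

    def regime_specs(self) -> list[tuple[int, list[str]]]:
        """Clade specs (regime id, two spanning tips) for re-painting."""
        specs = []
        for name, regime in (("monocot", 1), ("bep", 2)):
            node = self.clades[name]
            tips = [v for v in self.tree.subtree_nodes(node)
                    if not self.tree.children[v]]
            labels = [self.tree.labels[t] for t in tips]
            specs.append((regime, [labels[0], labels[-1]]))
        return specs

    def truth(self) -> dict:
        c = self.config
        return {
            "alpha": c.alpha, "sigma2": c.sigma2, "theta": list(c.theta),
            "z0": c.theta[0], "c4_offset": c.c4_offset,
            "cam_offset": c.cam_offset,
            "channels": {k: vars(v) for k, v in c.channels.items()},
            "latent": self.latent.to_dict(),
            "seed": c.seed,
        }


# ---------------------------------------------------------------------------
# Yule tree


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    unit_branch_lengths: bool = False,
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, deterministic under seed.

    Lineages split at exponential waiting times until ``n_tips`` are
    extant, then all are extended by one further waiting time so terminal
    branches have positive length.  ``unit_branch_lengths`` replaces every
    branch length with 1 afterwards (the topology-only convention).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, None, None]  # split time of internal nodes
    active = [1, 2]            # lineages awaiting their end time
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        pick = active.pop(rng.integers(len(active)))
        birth[pick] = t
        for _ in range(2):
            parent.append(pick)
            birth.append(None)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    blen = np.zeros(len(parent))
    labels = {}
    tip_no = 0
    for v in range(1, len(parent)):
        end = birth[v] if birth[v] is not None else t_end
        blen[v] = end - birth[parent[v]]
        if birth[v] is None:
            tip_no += 1
            labels[v] = f"sp{tip_no:03d}"
    if unit_branch_lengths:
        blen = np.where(np.arange(len(parent)) == 0, 0.0, 1.0)
    return Phylogeny(np.array(parent), blen, labels)


# ---------------------------------------------------------------------------
# Lineage / regime / growth-form / pathway assignment

_NON_MONOCOT_FRACTIONS = (
    ("Lycopod", 0.09),
    ("Fern", 0.15),
    ("Gymnosperm", 0.10),
    ("Magnoliid", 0.05),
    # Eudicot takes the remainder
)

_FORM_PROBS = (("tree", 0.40), ("shrub", 0.25), ("forb_herb", 0.30),
               ("climbing_vine", 0.05))


def _find_clade(
    tree: Phylogeny,
    within: int,
    target: int,
    min_size: int,
    max_size: int,
) -> int:
    """Internal node under ``within`` whose tip count is closest to target."""
    best, best_err = None, None
    for v in tree.subtree_nodes(within):
        if v == within or not tree.children[v]:
            continue
        size = sum(1 for u in tree.subtree_nodes(v) if not tree.children[u])
        if not (min_size <= size <= max_size):
            continue
        err = abs(size - target)
        if best_err is None or err < best_err:
            best, best_err = v, err
    if best is None:
        raise ValueError(
            f"no clade of {min_size}..{max_size} tips (target {target}) "
            "found; try a larger tree or different fractions"
        )
    return best


def assign_structure(
    tree: Phylogeny, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, RegimePainting, dict[str, int]]:
    """Lineage labels, regime painting, growth forms and pathways.

    Monocot, Poales and BEP analogs are nested clades chosen by tip count
    (within a factor of two of the requested fraction); graminoids occur
    only inside the Poales clade; other growth forms are assigned
    independently of lineage; C4 appears only among non-BEP graminoids and
    CAM among eudicots.
    """
    if rng is None:
        rng = stage_rng(config.seed, "structure")
    n = tree.n_tips

    def clade_tips(node: int) -> list[str]:
        return [tree.labels[v] for v in tree.subtree_nodes(node)
                if not tree.children[v]]

    t_mono = round(config.monocot_fraction * n)
    monocot = _find_clade(tree, 0, t_mono,
                          max(t_mono // 2, 8), min(t_mono * 2, n - 10))
    t_poal = round(config.poales_fraction * n)
    poales = _find_clade(tree, monocot, t_poal,
                         max(t_poal // 2, 5),
                         min(t_poal * 2, len(clade_tips(monocot)) - 2))
    t_bep = round(config.bep_fraction * n)
    bep = _find_clade(tree, poales, t_bep,
                      max(t_bep // 2, 2),
                      min(t_bep * 2, len(clade_tips(poales)) - 2))

    mono_tips = set(clade_tips(monocot))
    poal_tips = set(clade_tips(poales))
    bep_tips = set(clade_tips(bep))

    lineage: dict[str, str] = {}
    for sp in mono_tips:
        if sp in bep_tips:
            lineage[sp] = "BEP"
        elif sp in poal_tips:
            lineage[sp] = "PoalesMinus"
        else:
            lineage[sp] = "MonocotMinus"
    # non-monocot tips are split into grade-like blocks in tree order
    others = [tree.labels[v] for v in tree.tips if tree.labels[v] not in mono_tips]
    pos = 0
    for name, frac in _NON_MONOCOT_FRACTIONS:
        size = max(2, round(frac * len(others)))
        for sp in others[pos:pos + size]:
            lineage[sp] = name
        pos += size
    for sp in others[pos:]:
        lineage[sp] = "Eudicot"
    counts = pd.Series(lineage).value_counts()
    if counts.min() < 2 or len(counts) < 8:
        raise ValueError(
            "lineage assignment produced a class with < 2 species; "
            "increase n_tips"
        )

    painting = paint_regimes(
        tree,
        [(1, [clade_tips(monocot)[0], clade_tips(monocot)[-1]]),
         (2, [clade_tips(bep)[0], clade_tips(bep)[-1]])],
        root_regime=0,
    )

    forms, probs = zip(*_FORM_PROBS)
    growth_form: dict[str, str] = {}
    for sp in [tree.labels[v] for v in tree.tips]:
        if sp in poal_tips:
            growth_form[sp] = "graminoid"
        else:
            growth_form[sp] = str(rng.choice(forms, p=probs))

    pathway = {sp: "C3" for sp in lineage}
    poales_minus = sorted(poal_tips - bep_tips)
    n_c4 = min(config.n_c4, len(poales_minus))
    for sp in rng.choice(poales_minus, size=n_c4, replace=False):
        pathway[str(sp)] = "C4"
    eudicots = sorted(sp for sp, l in lineage.items() if l == "Eudicot")
    n_cam = min(config.n_cam, len(eudicots))
    for sp in rng.choice(eudicots, size=n_cam, replace=False):
        pathway[str(sp)] = "CAM"

    order = [tree.labels[v] for v in tree.tips]
    labels = pd.DataFrame(
        {"lineage": pd.Series(lineage), "growth_form": pd.Series(growth_form),
         "pathway": pd.Series(pathway)}
    ).loc[order]
    labels.index.name = "species"
    return labels, painting, {"monocot": monocot, "poales": poales, "bep": bep}


# ---------------------------------------------------------------------------
# Full study


def _invert_epsilon(eps: float, dD_source: float) -> float:
    """Wax delta-D giving the stated fractionation against a source water."""
    return (eps / 1000.0 + 1.0) * (dD_source + 1000.0) - 1000.0


def simulate_study(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic study (tree, labels, waxes, waters)."""
    if config is None:
        config = SyntheticConfig()
    tree = simulate_tree(
        config.n_tips, config.birth_rate,
        seed=stage_rng(config.seed, "tree").integers(2**31),
        unit_branch_lengths=config.unit_branch_lengths,
    )
    labels, painting, clades = assign_structure(tree, config)
    latent = simulate_ou(
        tree, painting, config.alpha, config.sigma2,
        np.array(config.theta), z0=config.theta[0],
        seed=stage_rng(config.seed, "trait").integers(2**31),
    )

    rng_c = stage_rng(config.seed, "compounds")
    rng_w = stage_rng(config.seed, "water")
    rng_m = stage_rng(config.seed, "missing")

    order = list(latent.index)
    path_shift = labels["pathway"].map(
        {"C3": 0.0, "C4": config.c4_offset, "CAM": config.cam_offset}
    ).loc[order]

    class_u = rng_c.normal(0.0, config.class_factor_sd, size=len(order)) \
        if config.class_factor_sd > 0 else np.zeros(len(order))
    acid_ids = {c.id for c in ACIDS}
    eps = {}
    for comp in CANONICAL_COMPOUNDS:
        ch = config.channels[comp.id]
        noise = rng_c.normal(0.0, ch.noise_sd, size=len(order)) \
            if ch.noise_sd > 0 else np.zeros(len(order))
        sign = 1.0 if comp.id in acid_ids else -1.0
        eps[comp.id] = (ch.intercept + ch.slope * latent.loc[order].to_numpy()
                        + path_shift.to_numpy() + sign * class_u + noise)
    eps = pd.DataFrame(eps, index=order)

    no_xylem = labels["lineage"].isin(["Fern", "Lycopod"]).loc[order]
    xylem = pd.Series(
        rng_w.normal(config.xylem_mean, config.xylem_sd, size=len(order)),
        index=order,
    )
    xylem[no_xylem] = np.nan
    source = xylem.fillna(config.environ)
    leafwater = source + config.leafwater_evap_offset
    leafwater[labels["growth_form"].loc[order] == "graminoid"] += \
        config.graminoid_leafwater_extra

    wax = pd.DataFrame(index=order)
    for comp in CANONICAL_COMPOUNDS:
        wax[f"dD_{comp.id}"] = [
            _invert_epsilon(eps.at[sp, comp.id], source[sp]) for sp in order
        ]
    if config.missing_rate > 0:
        mask = rng_m.random(wax.shape) < config.missing_rate
        # keep at least one compound per plant
        for i in range(mask.shape[0]):
            if mask[i].all():
                mask[i, rng_m.integers(mask.shape[1])] = False
        wax = wax.mask(mask)

    table = pd.concat([labels.loc[order], wax], axis=1)
    table["dD_xylem"] = xylem
    table["dD_leafwater"] = leafwater
    table["dD_environ"] = config.environ
    table.index.name = "species"

    samples = []
    for sp, row in table.iterrows():
        dD_wax = {c.id: float(row[f"dD_{c.id}"]) for c in CANONICAL_COMPOUNDS
                  if np.isfinite(row[f"dD_{c.id}"])}
        samples.append(SpeciesSample(
            species=str(sp), dD_wax=dD_wax,
            dD_environ=float(row["dD_environ"]),
            dD_xylem=float(row["dD_xylem"]) if np.isfinite(row["dD_xylem"]) else None,
            dD_leafwater=float(row["dD_leafwater"]),
            lineage=row["lineage"], growth_form=row["growth_form"],
            pathway=row["pathway"],
        ))
    return SyntheticDataset(
        samples=samples, table=table.reset_index(), tree=tree,
        painting=painting, labels=labels, latent=latent.loc[order],
        epsilon_true=eps, config=config, clades=clades,
    )
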