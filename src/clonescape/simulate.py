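"""Spatially explicit simulation of partially clonal benthic populations.

The generator emulates the biology of a fissiparous holothurian: founder
genets settle in a circular arena; asexual reproduction by transverse fission
(cold seasons) copies genotypes in place, each half regenerating at half the
parent's body size, with rare stepwise somatic mutation (+/- one repeat unit
per locus); sexual recruitment (warm seasons) draws new diploid genotypes from
the population's gamete pool; uniform mortality and an optional carrying
capacity keep the population in check. Body sizes follow a von Bertalanffy
growth curve; fission resets size to half. Every individual keeps its true
genet label, giving downstream clone identification a known ground truth.

Sampling mirrors a nested circular-plot design: four concentric annuli
(radii 5, 10, 20, 40 m), 16 individuals per annulus picked as the nearest
not-yet-sampled individual to random grid coordinates (10 degree angle steps,
10 cm radius steps), i.e. 64 individuals per station.

``simulate_study`` assembles a full multi-site, two-season, two-period survey
in that design (three high-density sites with two 64-sample stations, three
haphazardly sampled low-density sites) and is the package's no-download test
bed for the end-to-end pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genotype_io import LocusDef, LocusGenotype, SampleRecord, SampleTable

__all__ = [
    "SimulationParams",
    "GrowthModelParams",
    "SamplingDesign",
    "von_bertalanffy_length",
    "simulate_clonal_population",
    "nested_circular_sampling",
    "inject_missing",
    "simulate_study",
]


@dataclass(frozen=True)
class GrowthModelParams:
    """Von Bertalanffy growth parameters (length in mm, time in years)."""

    l_inf_mm: float = 342.24
    k: float = 0.45
    t0: float = -0.25


def von_bertalanffy_length(
    t_years: float, g: GrowthModelParams = GrowthModelParams()
) -> float:
    """Body length in cm at age ``t_years``: L_inf (1 - e^(-k (t - t0))) / 10."""
    return g.l_inf_mm * (1.0 - np.exp(-g.k * (t_years - g.t0))) / 10.0


def _vb_inverse(length_cm: float | np.ndarray, g: GrowthModelParams) -> np.ndarray:
    frac = np.clip(np.asarray(length_cm) * 10.0 / g.l_inf_mm, 0.0, 1.0 - 1e-12)
    return g.t0 - np.log(1.0 - frac) / g.k


@dataclass(frozen=True)
class SamplingDesign:
    """Nested circular plots: annuli between successive radii, a fixed number
    of random grid coordinates per annulus."""

    radii_m: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0)
    per_strip: int = 16
    angle_increment_deg: float = 10.0
    radius_increment_m: float = 0.1

    def __post_init__(self) -> None:
        if list(self.radii_m) != sorted(set(self.radii_m)):
            raise ValueError("radii must be strictly increasing")

    @property
    def target_total(self) -> int:
        return self.per_strip * len(self.radii_m)


@dataclass
class SimulationParams:
    """Knobs of the partial-clonality simulation.

    Rates are per season (two seasons per year, cold first). Defaults emulate
    a dense fissiparous aggregation: a 9-locus panel with 2-9 alleles per
    locus, fission in roughly half the individuals each cold season, a trickle
    of sexual recruits each warm season, heterozygote-excess founders, and a
    per-genotype missing-data rate of ~0.1%.
    """

    n_loci: int = 9
    alleles_per_locus: tuple[int, int] = (2, 9)
    founder_count: int = 8
    initial_population: int | None = None  # None: founders start as singletons
    clone_size_alpha: float = 0.3  # Dirichlet concentration of initial clone sizes
    arena_radius_m: float = 80.0
    n_seasons: int = 8
    fission_rate: float = 0.45
    sexual_recruitment_rate: float = 10.0
    mortality_rate: float = 0.08
    carrying_capacity: int | None = None
    fission_displacement_m: float = 5.0
    somatic_mutation_rate: float = 1e-4
    missing_rate: float = 0.0012
    motif_length: int = 1
    founder_fis: float = -0.5
    clone_spread_m: float | None = None  # None: ramets placed uniformly
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("fission_rate", "mortality_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sexual_recruitment_rate < 0:
            raise ValueError("sexual_recruitment_rate must be >= 0")
        if not -1.0 <= self.founder_fis <= 1.0:
            raise ValueError("founder_fis must be in [-1, 1]")
        lo, hi = self.alleles_per_locus
        if not 2 <= lo <= hi:
            raise ValueError("alleles_per_locus must be a (low, high) pair with low >= 2")


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


@dataclass
class _State:
    xy: np.ndarray  # (N, 2)
    genos: np.ndarray  # (N, L, 2) allele sizes, sorted within locus
    genet: np.ndarray  # (N,) int genet index
    t_eff: np.ndarray  # (N,) effective growth age in years
    next_genet: int

    @property
    def n(self) -> int:
        return self.xy.shape[0]


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _founder_frequencies(
    rng: np.random.Generator, params: SimulationParams
) -> list[tuple[np.ndarray, np.ndarray]]:
    lo, hi = params.alleles_per_locus
    pools = []
    for _ in range(params.n_loci):
        k = int(rng.integers(lo, hi + 1))
        sizes = 100 + params.motif_length * np.arange(k, dtype=np.int64)
        probs = rng.dirichlet(np.ones(k))
        pools.append((sizes, probs))
    return pools


def _draw_diploid(
    rng: np.random.Generator,
    pools: Sequence[tuple[np.ndarray, np.ndarray]],
    n: int,
    fis: float = 0.0,
) -> np.ndarray:
    """(n, L, 2) genotypes. Negative ``fis`` mixes in forced heterozygotes,
    positive ``fis`` forced homozygotes, on top of Hardy-Weinberg draws."""
    L = len(pools)
    out = np.empty((n, L, 2), dtype=np.int64)
    for j, (alleles, probs) in enumerate(pools):
        draws = rng.choice(alleles, size=(n, 2), p=probs)
        if fis > 0:
            force = rng.random(n) < fis
            draws[force, 1] = draws[force, 0]
        elif fis < 0 and alleles.size > 1:
            force = rng.random(n) < -fis
            same = draws[:, 0] == draws[:, 1]
            for i in np.flatnonzero(force & same):
                others = alleles[alleles != draws[i, 0]]
                op = probs[alleles != draws[i, 0]]
                draws[i, 1] = rng.choice(others, p=op / op.sum())
        out[:, j, :] = np.sort(draws, axis=1)
    return out


def _current_pools(genos: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    pools = []
    for j in range(genos.shape[1]):
        alleles, counts = np.unique(genos[:, j, :], return_counts=True)
        pools.append((alleles, counts / counts.sum()))
    return pools


def _initial_state(params: SimulationParams, rng: np.random.Generator) -> _State:
    pools = _founder_frequencies(rng, params)
    founders = _draw_diploid(rng, pools, params.founder_count, fis=params.founder_fis)
    if params.initial_population is None:
        counts = np.ones(params.founder_count, dtype=int)
    else:
        fracs = rng.dirichlet(
            np.full(params.founder_count, params.clone_size_alpha)
        )
        counts = rng.multinomial(params.initial_population, fracs)
        counts = np.maximum(counts, 1)
    genos = np.repeat(founders, counts, axis=0)
    genet = np.repeat(np.arange(params.founder_count), counts)
    n = genos.shape[0]
    if params.clone_spread_m is None:
        xy = _uniform_disc(rng, n, params.arena_radius_m)
    else:
        centres = _uniform_disc(rng, params.founder_count, params.arena_radius_m)
        xy = np.repeat(centres, counts, axis=0) + rng.normal(
            scale=params.clone_spread_m, size=(n, 2)
        )
    ages = rng.uniform(0.5, 6.0, size=n)
    return _State(
        xy=xy,
        genos=genos,
        genet=genet,
        t_eff=ages,
        next_genet=params.founder_count,
    )


def _season_step(
    state: _State,
    params: SimulationParams,
    rng: np.random.Generator,
    season: str,
    growth: GrowthModelParams,
) -> _State:
    xy, genos, genet, t_eff = state.xy, state.genos, state.genet, state.t_eff
    next_genet = state.next_genet
    if season == "cold" and state.n:
        fiss = rng.random(state.n) < params.fission_rate
        idx = np.flatnonzero(fiss)
        if idx.size:
            child_xy = xy[idx] + rng.normal(
                scale=params.fission_displacement_m, size=(idx.size, 2)
            )
            radius = np.hypot(child_xy[:, 0], child_xy[:, 1])
            over = radius > params.arena_radius_m
            child_xy[over] *= (params.arena_radius_m / radius[over])[:, None]
            child_genos = genos[idx].copy()
            mut = rng.random((idx.size, params.n_loci)) < params.somatic_mutation_rate
            for i, j in zip(*np.nonzero(mut)):
                which = rng.integers(2)
                step = params.motif_length * (1 if rng.random() < 0.5 else -1)
                child_genos[i, j, which] = max(
                    params.motif_length, child_genos[i, j, which] + step
                )
                child_genos[i, j] = np.sort(child_genos[i, j])
            # fission halves the body; both halves regenerate from half size
            half_t = _vb_inverse(
                np.array(
                    [von_bertalanffy_length(t, growth) / 2.0 for t in t_eff[idx]]
                ),
                growth,
            )
            t_eff = t_eff.copy()
            t_eff[idx] = half_t
            xy = np.vstack([xy, child_xy])
            genos = np.vstack([genos, child_genos])
            genet = np.concatenate([genet, genet[idx]])
            t_eff = np.concatenate([t_eff, half_t])
    elif season == "warm" and state.n:
        n_recruits = int(rng.poisson(params.sexual_recruitment_rate))
        if n_recruits:
            pools = _current_pools(genos)
            rec_genos = _draw_diploid(rng, pools, n_recruits)
            xy = np.vstack([xy, _uniform_disc(rng, n_recruits, params.arena_radius_m)])
            genos = np.vstack([genos, rec_genos])
            genet = np.concatenate(
                [genet, np.arange(next_genet, next_genet + n_recruits)]
            )
            t_eff = np.concatenate([t_eff, np.full(n_recruits, 0.1)])
            next_genet += n_recruits

    n = xy.shape[0]
    keep = rng.random(n) >= params.mortality_rate
    if params.carrying_capacity is not None and keep.sum() > params.carrying_capacity:
        alive = np.flatnonzero(keep)
        kill = rng.choice(
            alive, size=keep.sum() - params.carrying_capacity, replace=False
        )
        keep[kill] = False
    xy, genos, genet, t_eff = xy[keep], genos[keep], genet[keep], t_eff[keep]
    t_eff = t_eff + 0.5  # half a year per season
    return _State(xy=xy, genos=genos, genet=genet, t_eff=t_eff, next_genet=next_genet)


def _state_to_table(
    state: _State,
    params: SimulationParams,
    growth: GrowthModelParams,
    site: str = "sim",
    season: str = "",
    period: str = "",
) -> SampleTable:
    panel = [LocusDef(f"L{j + 1}", params.motif_length) for j in range(params.n_loci)]
    records = []
    for i in range(state.n):
        genotype = tuple(
            LocusGenotype(int(state.genos[i, j, 0]), int(state.genos[i, j, 1]))
            for j in range(params.n_loci)
        )
        records.append(
            SampleRecord(
                sample_id=f"ind{i:06d}",
                site=site,
                season=season,
                period=period,
                x=float(state.xy[i, 0]),
                y=float(state.xy[i, 1]),
                size_cm=float(von_bertalanffy_length(state.t_eff[i], growth)),
                genotype=genotype,
                genet_id=f"g{state.genet[i]:04d}",
            )
        )
    return SampleTable(panel, records)


def simulate_clonal_population(
    params: SimulationParams,
    growth: GrowthModelParams = GrowthModelParams(),
    snapshots: Sequence[int] = (),
) -> SampleTable | dict[int, SampleTable]:
    """Run the seasonal simulation.

    Returns the final population as a :class:`SampleTable` (with ground-truth
    ``genet_id`` on every record), or, when ``snapshots`` lists season indices
    (0-based, evaluated after that season's step), a dict of tables. Missing
    data is injected at ``params.missing_rate`` into returned tables.
    """
    rng = np.random.default_rng(params.seed)
    state = _initial_state(params, rng)
    taken: dict[int, SampleTable] = {}
    for s in range(params.n_seasons):
        season = "cold" if s % 2 == 0 else "warm"
        state = _season_step(state, params, rng, season, growth)
        if state.n == 0:
            warnings.warn(f"population went extinct at season {s}")
            break
        if s in snapshots:
            taken[s] = _state_to_table(state, params, growth, season=season)
    final = _state_to_table(
        state, params, growth, season="cold" if (params.n_seasons - 1) % 2 == 0 else "warm"
    )
    if params.missing_rate > 0:
        final = inject_missing(final, params.missing_rate, seed=rng.integers(2**31))
        taken = {
            k: inject_missing(t, params.missing_rate, seed=rng.integers(2**31))
            for k, t in taken.items()
        }
    if snapshots:
        return taken
    return final


# ---------------------------------------------------------------------------
# sampling designs
# ---------------------------------------------------------------------------


def nested_circular_sampling(
    pop: SampleTable,
    centre: tuple[float, float] = (0.0, 0.0),
    design: SamplingDesign = SamplingDesign(),
    seed: int | None = None,
) -> SampleTable:
    """Sample a station by nested circular plots around ``centre``.

    For each annulus between successive design radii, ``per_strip`` random
    grid coordinates are drawn (angles on the angle grid, radii on the radius
    grid, uniform over the annulus's radial band) and the nearest
    not-yet-sampled individual to each coordinate is taken. Returned records
    carry coordinates relative to ``centre``. Annuli holding fewer individuals
    than requested yield fewer records, with a warning.
    """
    rng = np.random.default_rng(seed)
    if not all(r.has_coordinates for r in pop.records):
        raise ValueError("nested sampling requires coordinates on every record")
    xy = np.array([(r.x, r.y) for r in pop.records], dtype=float)
    cx, cy = centre
    available = np.ones(len(pop.records), dtype=bool)
    chosen: list[int] = []
    bounds = [(0.0, design.radii_m[0])] + list(
        zip(design.radii_m[:-1], design.radii_m[1:])
    )
    n_angles = int(round(360.0 / design.angle_increment_deg))
    dist_from_centre = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
    for lo, hi in bounds:
        in_annulus = (dist_from_centre >= lo) & (dist_from_centre < hi) & available
        n_here = int(in_annulus.sum())
        if n_here < design.per_strip:
            warnings.warn(
                f"annulus {lo}-{hi} m holds {n_here} unsampled individuals "
                f"(< {design.per_strip})"
            )
        radii_grid = np.arange(lo, hi, design.radius_increment_m)
        radii_grid = radii_grid[radii_grid >= lo]
        for _ in range(design.per_strip):
            in_annulus = (dist_from_centre >= lo) & (dist_from_centre < hi) & available
            if not in_annulus.any():
                break
            theta = np.deg2rad(rng.integers(n_angles) * design.angle_increment_deg)
            r = float(rng.choice(radii_grid))
            tx, ty = cx + r * np.cos(theta), cy + r * np.sin(theta)
            cand = np.flatnonzero(in_annulus)
            d = np.hypot(xy[cand, 0] - tx, xy[cand, 1] - ty)
            pick = cand[int(np.argmin(d))]
            chosen.append(pick)
            available[pick] = False
    records = [
        replace(pop.records[i], x=float(xy[i, 0] - cx), y=float(xy[i, 1] - cy))
        for i in chosen
    ]
    return SampleTable(pop.panel, records)


def inject_missing(
    table: SampleTable, missing_rate: float, seed: int | None = None
) -> SampleTable:
    """Set each (individual, locus) genotype missing independently with the
    given probability (both alleles of the pair)."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if missing_rate == 0.0:
        return table
    rng = np.random.default_rng(seed)
    from .genotype_io import MISSING

    records = []
    for rec in table.records:
        mask = rng.random(len(table.panel)) < missing_rate
        if mask.any():
            genotype = tuple(
                MISSING if m else g for g, m in zip(rec.genotype, mask)
            )
            records.append(replace(rec, genotype=genotype))
        else:
            records.append(rec)
    return SampleTable(table.panel, records)


# ---------------------------------------------------------------------------
# full survey emulation
# ---------------------------------------------------------------------------

_STUDY_SITES = {
    # site: (density class, sampled periods, per-date sample size for haphazard)
    "HIGH1": ("high", ("T0", "T2"), None),
    "HIGH2": ("high", ("T0", "T2"), None),
    "HIGH3": ("high", ("T0", "T2"), None),
    "LOW1": ("low", ("T0",), 32),
    "LOW2": ("low", ("T0", "T2"), None),  # 32 at T0, 48 at T2
    "LOW3": ("low", ("T2",), 48),
}

#: observation-season index of each (period, season) sampling date, after a
#: one-year burn-in (seasons 0-1); a skipped year separates T0 from T2.
_STUDY_DATES = {("T0", "cold"): 2, ("T0", "warm"): 3, ("T2", "cold"): 8, ("T2", "warm"): 9}


def simulate_study(
    seed: int | None = None,
    missing_rate: float = 0.0012,
    station_offset_m: float = 40.0,
) -> SampleTable:
    """Simulate the full multi-site survey: three high-density sites (two
    nested-circular-plot stations of 64 at T0, one at T2, both seasons) and
    three low-density sites (32 or 48 haphazard samples per date). Each site
    is an independent population: clones do not disperse between sites. The
    returned table carries ground-truth genet labels and missing data injected
    at ``missing_rate`` per (individual, locus).
    """
    root = np.random.default_rng(seed)
    all_records: list[SampleRecord] = []
    panel: list[LocusDef] | None = None
    for site, (density, periods, hap_n) in _STUDY_SITES.items():
        site_seed = int(root.integers(2**31))
        rng = np.random.default_rng(site_seed)
        if density == "high":
            params = SimulationParams(
                initial_population=5000,
                carrying_capacity=5000,
                n_seasons=10,
                missing_rate=0.0,
                sexual_recruitment_rate=15.0,
                seed=int(rng.integers(2**31)),
            )
        else:
            params = SimulationParams(
                initial_population=900,
                carrying_capacity=900,
                n_seasons=10,
                missing_rate=0.0,
                sexual_recruitment_rate=5.0,
                seed=int(rng.integers(2**31)),
            )
        dates = [
            (p, s)
            for (p, s), idx in _STUDY_DATES.items()
            if p in periods
        ]
        snap_idx = sorted({_STUDY_DATES[d] for d in dates})
        tables = simulate_clonal_population(params, snapshots=snap_idx)
        if panel is None:
            panel = tables[snap_idx[0]].panel
        for period, season in dates:
            snap = tables[_STUDY_DATES[(period, season)]]
            if density == "high":
                stations = (
                    {"S1": (-station_offset_m, 0.0), "S2": (station_offset_m, 0.0)}
                    if period == "T0"
                    else {"S1": (-station_offset_m, 0.0)}
                )
                for station, centre in stations.items():
                    sample = nested_circular_sampling(
                        snap, centre=centre, seed=int(rng.integers(2**31))
                    )
                    for rec in sample.records:
                        all_records.append(
                            replace(
                                rec,
                                sample_id=f"{site}_{station}_{period}_{season}_{rec.sample_id}",
                                site=site,
                                station=station,
                                season=season,
                                period=period,
                                genet_id=f"{site}-{rec.genet_id}",
                            )
                        )
            else:
                n_take = hap_n if hap_n is not None else (32 if period == "T0" else 48)
                idx = rng.choice(len(snap.records), size=min(n_take, len(snap.records)), replace=False)
                for i in idx:
                    rec = snap.records[int(i)]
                    all_records.append(
                        replace(
                            rec,
                            sample_id=f"{site}_{period}_{season}_{rec.sample_id}",
                            site=site,
                            station="",
                            season=season,
                            period=period,
                            genet_id=f"{site}-{rec.genet_id}",
                        )
                    )
    assert panel is not None
    table = SampleTable(panel, all_records)
    return inject_missing(table, missing_rate, seed=int(root.integers(2**31)))
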