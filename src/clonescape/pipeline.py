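"""End-to-end orchestration of the clonal-structure analysis.

``run_full_pipeline`` chains the stages — completeness filtering, clone
identification and P_sex calls, MLL collapse, per-population clonal and
genetic diversity, spatial indices, the genotype network with its percolation
threshold, pairwise differentiation (spatial, seasonal, inter-annual, and
genet-level between pooled high-density sites), and the sexual-only richness
null — writing one delimited text table per stage plus a ``run.log`` that
records the seeds and parameters needed to reproduce every numeric cell.

Populations are defined by the (site, station, season, period) key; stations
collapse into their site when empty (haphazardly sampled sites).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .clones import call_clones, collapse_mll, identify_mlgs, mll_threshold, probability_of_identity
from .diversity import CloneSummary, clone_summary
from .genotype_io import SampleTable, drop_incomplete
from .networks import build_network, distance_matrix, percolation_threshold
from .nullsim import null_richness_test
from .popgen import (
    allele_frequencies,
    diversity_summary,
    pairwise_differentiation,
)

__all__ = ["AnalysisConfig", "run_population_summary", "run_full_pipeline", "significance_stars"]


@dataclass
class AnalysisConfig:
    """Shared knobs of a pipeline run; every output header logs them."""

    alpha: float = 0.05
    n_perm: int = 1000
    n_rep: int = 1000
    seed: int = 0
    level: str = "ramet"
    group_by: str = "station"  # or "site": pool stations within site
    min_population_size: int = 2

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2**31)


def significance_stars(p: float) -> str:
    """.05 / .01 / .001 star convention."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _grouped(table: SampleTable, config: AnalysisConfig) -> dict:
    if config.group_by == "site":
        merged: dict = {}
        for key, sub in table.by_population().items():
            site, _, season, period = key
            merged.setdefault((site, "", season, period), []).extend(sub.records)
        return {k: SampleTable(table.panel, v) for k, v in merged.items()}
    return table.by_population()


def run_population_summary(table: SampleTable, config: AnalysisConfig) -> pd.DataFrame:
    """One row per population: N, N_MLG, R, J', beta, A_c, E_e, N_a, N_ap,
    H_O (SE), H_E (SE), F_IS with significance stars. Populations smaller
    than the configured minimum are skipped with a warning."""
    complete, _ = drop_incomplete(table)
    pops = _grouped(complete, config)
    rows = []
    for i, (key, pop) in enumerate(pops.items()):
        if len(pop) < config.min_population_size:
            warnings.warn(f"population {key} has N={len(pop)} < "
                          f"{config.min_population_size}; skipped")
            continue
        site, station, season, period = key
        spatial = bool(station) and all(r.has_coordinates for r in pop.records)
        cs = clone_summary(
            pop,
            n_perm=config.n_perm,
            seed=config.stage_seed(100 + i),
            spatial=spatial,
        )
        others = [sub for k2, sub in pops.items() if k2 != key and len(sub) >= 2]
        ds = diversity_summary(
            pop,
            comparison_set=others,
            n_perm=config.n_perm,
            seed=config.stage_seed(200 + i),
        )
        rows.append(
            {
                "site": site,
                "station": station,
                "season": season,
                "period": period,
                "N": cs.n,
                "N_MLG": cs.g,
                "R": cs.r,
                "J_prime": cs.j_prime,
                "beta": cs.beta,
                "A_c": cs.a_c,
                "Ac_p": cs.ac_p,
                "E_e": cs.e_e,
                "Ee_p": cs.ee_p,
                "N_a": ds.n_a,
                "N_ap": ds.n_ap,
                "H_O": ds.h_o,
                "H_O_se": ds.h_o_se,
                "H_E": ds.h_e,
                "H_E_se": ds.h_e_se,
                "F_IS": ds.f_is,
                "hwe_p": ds.hwe_p,
                "F_IS_sig": significance_stars(ds.hwe_p),
            }
        )
    return pd.DataFrame(rows)


def _differentiation_rows(table: SampleTable, config: AnalysisConfig) -> pd.DataFrame:
    """Pairwise F_ST / D_est: spatial pairs per sampling date, seasonal and
    inter-annual comparisons per site, and genet-level high-density site
    pairs pooled over dates."""
    complete, _ = drop_incomplete(table)
    pops = _grouped(complete, config)
    rows = []
    counter = 0

    def add(comparison, a_key, a_tab, b_key, b_tab, level):
        nonlocal counter
        if len(a_tab) < 2 or len(b_tab) < 2:
            return
        pd_res = pairwise_differentiation(
            a_tab,
            b_tab,
            n_perm=config.n_perm,
            seed=config.stage_seed(300 + counter),
            level=level,
        )
        counter += 1
        rows.append(
            {
                "comparison": comparison,
                "pop_a": "/".join(a_key),
                "pop_b": "/".join(b_key),
                "level": level,
                "fst": pd_res.fst,
                "fst_display": max(pd_res.fst, 0.0) if not np.isnan(pd_res.fst) else np.nan,
                "fst_p": pd_res.fst_p,
                "fst_sig": significance_stars(pd_res.fst_p),
                "dest": pd_res.dest,
                "dest_display": max(pd_res.dest, 0.0) if not np.isnan(pd_res.dest) else np.nan,
                "dest_p": pd_res.dest_p,
                "dest_sig": significance_stars(pd_res.dest_p),
            }
        )

    # spatial: all population pairs within each sampling date
    dates = sorted({(k[3], k[2]) for k in pops})
    for period, season in dates:
        keys = sorted(k for k in pops if (k[3], k[2]) == (period, season))
        for ka, kb in combinations(keys, 2):
            add("spatial", ka, pops[ka], kb, pops[kb], config.level)

    # seasonal: cold vs warm within site and period (stations pooled)
    def pooled(site, season=None, period=None) -> SampleTable:
        recs = [
            r
            for key, sub in pops.items()
            for r in sub.records
            if key[0] == site
            and (season is None or key[2] == season)
            and (period is None or key[3] == period)
        ]
        return SampleTable(complete.panel, recs) if recs else SampleTable(complete.panel, [])

    sites = sorted({k[0] for k in pops})
    periods = sorted({k[3] for k in pops})
    for site in sites:
        for period in periods:
            a = pooled(site, season="cold", period=period)
            b = pooled(site, season="warm", period=period)
            if len(a) >= 2 and len(b) >= 2:
                add(
                    "seasonal",
                    (site, "", "cold", period),
                    a,
                    (site, "", "warm", period),
                    b,
                    config.level,
                )
        if len(periods) >= 2:
            a = pooled(site, period=periods[0])
            b = pooled(site, period=periods[1])
            if len(a) >= 2 and len(b) >= 2:
                add(
                    "interannual",
                    (site, "", "", periods[0]),
                    a,
                    (site, "", "", periods[1]),
                    b,
                    config.level,
                )

    # high-density site pairs, all dates pooled, ramet and genet level
    high_sites = [s for s in sites if s.upper().startswith("HIGH")]
    for sa, sb in combinations(high_sites, 2):
        a, b = pooled(sa), pooled(sb)
        for level in ("ramet", "genet"):
            add("site_pooled", (sa, "", "", ""), a, (sb, "", "", ""), b, level)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_full_pipeline(
    table: SampleTable, outdir: str | Path, config: AnalysisConfig | None = None
) -> dict[str, Path]:
    """Run every stage and write the artifact directory. Any stage failure
    removes the partial outputs and raises a stage-named error."""
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"clonescape {__version__}",
        f"config: {asdict(config)}",
    ]
    outputs: dict[str, Path] = {}
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "completeness"
        complete, n_removed = drop_incomplete(table)
        log = [
            f"clonescape {__version__}",
            f"config: {asdict(config)}",
            f"records: {len(table)} total, {n_removed} removed (missing data), "
            f"{len(complete)} kept",
        ]

        stage = "clones"
        mlgs = identify_mlgs(complete)
        calls = {c.mlg_id: c for c in call_clones(complete, alpha=config.alpha)}
        freqs = allele_frequencies(complete)
        pid = probability_of_identity(freqs)
        clone_rows = []
        for m in mlgs:
            c = calls.get(m.mlg_id)
            clone_rows.append(
                {
                    "mlg_id": m.mlg_id,
                    "n_copies": m.n_copies,
                    "members": ";".join(m.member_ids),
                    "p_gen": c.p_gen if c else np.nan,
                    "p_sex": c.p_sex if c else np.nan,
                    "p_sex_fis": c.p_sex_fis if c else np.nan,
                    "distinct_events_flag": c.distinct_events_flag if c else False,
                }
            )
        path = outdir / "clones.tsv"
        _write_tsv(pd.DataFrame(clone_rows), path, header + [f"P_ID={pid.p_id:.4g}"])
        outputs["clones"] = path
        written.append(path)
        log.append(f"{len(mlgs)} distinct MLGs; P_ID={pid.p_id:.6g}")

        stage = "mll"
        dist = distance_matrix(mlgs, complete.panel)
        threshold = mll_threshold(dist)
        partition = collapse_mll(mlgs, dist, threshold)
        log.append(
            f"MLL threshold={threshold} mutation steps; "
            f"{partition.n_lineages} lineages from {len(mlgs)} MLGs"
        )

        stage = "summary"
        summary = run_population_summary(complete, config)
        path = outdir / "summary.tsv"
        _write_tsv(summary, path, header)
        outputs["summary"] = path
        written.append(path)

        stage = "spatial"
        spatial_cols = [
            "site", "station", "season", "period", "A_c", "Ac_p", "E_e", "Ee_p",
        ]
        path = outdir / "spatial.tsv"
        _write_tsv(summary[spatial_cols], path, header)
        outputs["spatial"] = path
        written.append(path)

        stage = "differentiation"
        diff = _differentiation_rows(complete, config)
        path = outdir / "fst_dest.tsv"
        _write_tsv(diff, path, header)
        outputs["differentiation"] = path
        written.append(path)

        stage = "nullsim"
        null_rows = []
        for i, (key, pop) in enumerate(_grouped(complete, config).items()):
            if len(pop) < 2:
                continue
            res = null_richness_test(
                pop, n_rep=config.n_rep, seed=config.stage_seed(500 + i)
            )
            null_rows.append(
                {
                    "site": key[0],
                    "station": key[1],
                    "season": key[2],
                    "period": key[3],
                    "R_obs": res.r_obs,
                    "R_sim_mean": res.r_sim_mean,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "n_rep": res.n_rep,
                    "seed": res.seed,
                }
            )
        path = outdir / "nullsim.tsv"
        _write_tsv(pd.DataFrame(null_rows), path, header)
        outputs["nullsim"] = path
        written.append(path)

        stage = "network"
        site_of = {}
        for m in mlgs:
            sites = [r.site for r in complete.records if r.sample_id in set(m.member_ids)]
            site_of[m.mlg_id] = max(set(sites), key=sites.count)
        net_summary = percolation_threshold(dist)
        g = build_network(
            dist,
            threshold=net_summary.dpe,
            node_attrs={
                m.mlg_id: {"n_copies": m.n_copies, "site": site_of[m.mlg_id]}
                for m in mlgs
            },
        )
        path = outdir / "net.graphml"
        nx.write_graphml(g, path)
        outputs["network"] = path
        written.append(path)
        path = outdir / "net_summary.tsv"
        _write_tsv(
            net_summary.curve().assign(
                dpe=net_summary.dpe,
                cc=net_summary.cc,
                n_components_below=net_summary.n_components,
            ),
            path,
            header,
        )
        outputs["network_summary"] = path
        written.append(path)
        log.append(
            f"network: Dpe={net_summary.dpe:.4g}, <CC>={net_summary.cc:.4g}, "
            f"{net_summary.n_components} clusters below Dpe"
        )

        stage = "log"
        path = outdir / "run.log"
        path.write_text("\n".join(log) + "\n")
        outputs["log"] = path
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
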