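"""End-to-end orchestration: simulate/load -> features -> cluster -> survival.

Every stage is a library call; this module sequences them, writes the
artifact files (features.csv, partition.csv, stability.json, per-domain
results.json, curves.csv, report.md) and enforces hermetic, reproducible
runs: all randomness flows from seeds named in the config, every parameter is
logged, and floats are rounded to 6 significant digits at write time so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import community, io, smoothing, survival, trajectory
from .errors import ConfigError, StimtrajError
from .simulate import CohortConfig, OutcomeSpec, SubgroupSpec, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str
    simulate: CohortConfig | None = None
    prescriptions_path: str | None = None
    subjects_path: str | None = None
    outcomes_path: str | None = None
    start_age_offset: float | None = None  # None: earliest start age in sample
    duration_threshold: float = 1.0  # mg/day
    louvain_seed: int = 0
    louvain_restarts: int = 20
    resolution: float = 1.0
    bootstrap_b: int = 100
    domains: tuple[str, ...] = survival.DOMAINS
    covariates: tuple[str, ...] = ()
    reference_group: str = "early_and_intense"
    matched_analysis: bool = False
    ties: str = "breslow"

    def __post_init__(self):
        if self.simulate is None:
            for p in (self.prescriptions_path, self.subjects_path, self.outcomes_path):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"input table missing: {p}")
        unknown = set(self.domains) - set(survival.DOMAINS)
        if unknown:
            raise ConfigError(f"unknown outcome domain(s): {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        sim = CohortConfig(
            subgroup_specs=[SubgroupSpec(**s) for s in sim.pop("subgroup_specs")],
            outcome_specs={
                k: OutcomeSpec(**v) for k, v in sim.pop("outcome_specs").items()
            },
            **sim,
        )
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"unknown config key(s): {sorted(bad)}")
    if "domains" in raw:
        raw["domains"] = tuple(raw["domains"])
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    return RunConfig(simulate=sim, **raw)


def _sig6(x):
    """Round floats to 6 significant digits, recursively, for byte-stable output."""
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    if isinstance(x, (np.floating,)):
        return float(f"{float(x):.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(_sig6(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write every artifact; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: data -------------------------------------------------------
    try:
        if config.simulate is not None:
            log.info("simulate: seed=%d", config.simulate.seed)
            prescriptions, subjects, outcomes = simulate_cohort(config.simulate)
            io.write_table(prescriptions, outdir / "prescriptions.csv",
                           io.PrescriptionRecord)
            io.write_table(subjects, outdir / "subjects.csv", io.SubjectRecord)
            io.write_table(outcomes, outdir / "outcomes.csv", io.OutcomeRecord)
            with open(outdir / "config.yaml", "w") as fh:
                yaml.safe_dump(_sig6(config.simulate.to_dict()), fh, sort_keys=True)
        else:
            prescriptions = io.read_prescriptions(config.prescriptions_path)
            subjects = io.read_subjects(config.subjects_path)
            outcomes = io.read_outcomes(config.outcomes_path)
    except StimtrajError as exc:
        raise type(exc)(f"[stage data] {exc}") from exc
    io.warn_untreated_with_prescriptions(prescriptions, subjects)
    log.info("data: %d prescriptions, %d subjects, %d outcomes",
             len(prescriptions), len(subjects), len(outcomes))

    # ---- stage: trajectories + features -----------------------------------
    try:
        adhd = [s for s in subjects if s.group_flag is not io.GroupFlag.CONTROL]
        recs_by_subject: dict[str, list] = {}
        for r in prescriptions:
            recs_by_subject.setdefault(r.subject_id, []).append(r)
        trajectories = [
            trajectory.build_daily_trajectory(recs_by_subject.get(s.subject_id, []), s)
            for s in adhd
        ]
        profiles, naive_ids = smoothing.build_profiles(
            trajectories, adhd,
            start_age_offset=config.start_age_offset,
            duration_threshold=config.duration_threshold,
        )
        smoothing.write_features(profiles, outdir / "features.csv")
    except StimtrajError as exc:
        raise type(exc)(f"[stage features] {exc}") from exc
    log.info("features: %d treated profiles (%d fallback), %d naive",
             len(profiles), sum(p.fallback for p in profiles), len(naive_ids))

    # ---- stage: community --------------------------------------------------
    try:
        z = community.standardize(profiles)
        graph = community.build_graph(z, node_ids=[p.subject_id for p in profiles])
        partition = community.louvain(
            graph, seed=config.louvain_seed,
            resolution=config.resolution, restarts=config.louvain_restarts,
        )
        stability = community.bootstrap_stability(
            profiles, b=config.bootstrap_b, seed=config.louvain_seed + 1,
            reference=partition,
        )
        assignment = community.label_subgroups(partition, profiles, naive_ids)
        community.write_partition(assignment, outdir / "partition.csv")
        _write_json(
            {
                "B": stability.b,
                "modal_k": stability.modal_k,
                "stability_fraction": stability.stability_fraction,
                "mean_Q": stability.mean_q,
                "sd_Q": stability.sd_q,
                "mean_ari_vs_full": stability.mean_ari,
                "replicates": [
                    {"k": int(k), "Q": float(q)}
                    for k, q in zip(stability.ks, stability.qs)
                ],
            },
            outdir / "stability.json",
        )
    except StimtrajError as exc:
        raise type(exc)(f"[stage community] {exc}") from exc
    log.info("community: k=%d Q=%.3f stability=%.3f",
             partition.k, partition.q, stability.stability_fraction)

    # ---- stage: survival ---------------------------------------------------
    groups = {sid: lbl for sid, _, lbl in assignment}
    group_sizes = {}
    for lbl in groups.values():
        group_sizes[lbl] = group_sizes.get(lbl, 0) + 1
    reference = config.reference_group
    if reference not in group_sizes:
        reference = max(group_sizes, key=group_sizes.get)
        log.warning("reference group %r absent; using largest group %r",
                    config.reference_group, reference)
    non_stim = survival.non_stimulant_users(prescriptions)

    domain_results = {}
    curve_rows = []
    try:
        for domain in config.domains:
            data = survival.make_survival_dataset(
                subjects, outcomes, groups, domain, non_stimulant_ids=non_stim
            )
            fit = survival.fit_cox(
                data, reference_group=reference,
                covariates=list(config.covariates),
                ties=config.ties,
            )
            chi2, df, p = survival.wald_group_test(fit)
            pairs = survival.pairwise_hazard_ratios(fit)
            events = data.groupby("group")["event"].agg(["sum", "count"])
            result = {
                "domain": domain,
                "n": fit.n,
                "events": int(fit.n_events),
                "clusters": fit.n_clusters,
                "reference_group": reference,
                "wald": {"chi2": chi2, "df": df, "p": p},
                "per_group_events": {
                    g: {"events": int(r["sum"]), "n": int(r["count"])}
                    for g, r in events.iterrows()
                },
                "pairwise": pairs.to_dict(orient="records"),
            }
            domain_results[domain] = {"fit": fit, "report": result}
            _write_json(result, outdir / f"results_{domain}.json")
            for g in fit.group_labels:
                ci = survival.cumulative_incidence(fit, g)
                for _, row in ci.iterrows():
                    curve_rows.append((domain, g, row["time"], row["cumulative_incidence"]))
        with open(outdir / "curves.csv", "w") as fh:
            fh.write("domain,group,time,cumulative_incidence\n")
            for dom, g, t, c in curve_rows:
                fh.write(f"{dom},{g},{t:.6g},{c:.6g}\n")
    except StimtrajError as exc:
        raise type(exc)(f"[stage survival] {exc}") from exc

    matched_report = None
    if config.matched_analysis:
        try:
            adhd_subjects = [s for s in subjects if s.subject_id in groups]
            match = survival.match_groups(adhd_subjects, groups)
            kept = set(match.selected_ids)
            m_groups = {sid: g for sid, g in groups.items() if sid in kept}
            data = survival.make_survival_dataset(
                subjects, outcomes, m_groups, config.domains[0],
                non_stimulant_ids=non_stim,
            )
            fit = survival.fit_cox(data, reference_group=reference, ties=config.ties)
            chi2, df, p = survival.wald_group_test(fit)
            matched_report = {
                "target_n": len(match.selected_ids) // len(group_sizes),
                "balance": match.balance.to_dict(orient="records"),
                "wald": {"chi2": chi2, "df": df, "p": p},
            }
            _write_json(matched_report, outdir / "results_matched.json")
        except StimtrajError as exc:
            raise type(exc)(f"[stage matched] {exc}") from exc

    report = {
        "group_sizes": group_sizes,
        "n_profiles": len(profiles),
        "n_naive": len(naive_ids),
        "n_fallback": int(sum(p.fallback for p in profiles)),
        "partition": {"k": partition.k, "Q": partition.q},
        "stability": {
            "B": stability.b,
            "modal_k": stability.modal_k,
            "stability_fraction": stability.stability_fraction,
            "mean_Q": stability.mean_q,
            "sd_Q": stability.sd_q,
        },
        "domains": {d: r["report"] for d, r in domain_results.items()},
        "matched": matched_report,
    }
    _write_report_md(report, profiles, groups, outdir / "report.md")
    report["fits"] = {d: r["fit"] for d, r in domain_results.items()}
    return report


def _write_report_md(report, profiles, groups, path):
    """Human-readable run summary: group sizes, feature means, stability, HRs."""
    by_group: dict[str, list] = {}
    for p in profiles:
        by_group.setdefault(groups[p.subject_id], []).append(p.as_vector())
    lines = ["# Pipeline run report", "", "## Group sizes", ""]
    for g, n in sorted(report["group_sizes"].items()):
        lines.append(f"- {g}: {n}")
    lines += ["", "## Treated-subgroup feature means", "",
              "| group | " + " | ".join(smoothing.FEATURE_NAMES) + " |",
              "|" + "---|" * 7]
    for g in sorted(by_group):
        m = np.mean(by_group[g], axis=0)
        lines.append("| " + g + " | " + " | ".join(f"{v:.6g}" for v in m) + " |")
    st = report["stability"]
    lines += [
        "",
        "## Community detection",
        "",
        f"- communities: k = {report['partition']['k']}, "
        f"Q = {report['partition']['Q']:.6g}",
        f"- bootstrap (B = {st['B']}): modal k = {st['modal_k']}, "
        f"stability = {st['stability_fraction']:.6g}, "
        f"mean Q = {st['mean_Q']:.6g} (SD {st['sd_Q']:.6g})",
        "",
        "## Survival",
        "",
    ]
    for d, r in sorted(report["domains"].items()):
        w = r["wald"]
        lines.append(
            f"### {d}: Wald chi2 = {w['chi2']:.6g} (df {w['df']}), p = {w['p']:.6g}"
        )
        lines.append("")
        lines.append("| group | versus | HR | 95% CI | p |")
        lines.append("|---|---|---|---|---|")
        for row in r["pairwise"]:
            lines.append(
                f"| {row['group']} | {row['versus']} | {row['hr']:.6g} "
                f"| {row['ci_low']:.6g}-{row['ci_high']:.6g} | {row['p']:.6g} |"
            )
        lines.append("")
    if report.get("matched"):
        w = report["matched"]["wald"]
        lines.append(
            f"## Matched sensitivity analysis: Wald chi2 = {w['chi2']:.6g}, "
            f"p = {w['p']:.6g}"
        )
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
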