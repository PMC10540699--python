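"""End-to-end pipeline: paradigm -> synthetic cohort -> spectral + ERP +
behavioral statistics -> JSON report with a reproducibility manifest.

Every stochastic stage consumes an explicit child seed spawned from the
master seed; rerunning with the same configuration reproduces all outputs
bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import erp_stats, io, spectral, synth
from .cluster_stats import Cluster
from .montage import channel_adjacency
from .paradigm import CONDITIONS, build_schedule, condition_halves, events_dataframe

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 6
    n_blocks: int = 6
    trials_per_block: int = 6
    analysis_fs_hz: float = 300.0
    n_perm: int = 300
    fwhm_mm: float = 5.0
    forming_p: float = 1e-3
    alpha: float = 0.05
    dss_n_keep: int = 8
    eeg: synth.SynthEEGParams = field(default_factory=synth.SynthEEGParams)
    behavior: synth.SynthBehaviorParams = field(
        default_factory=synth.SynthBehaviorParams)

    def __post_init__(self) -> None:
        for name in ("forming_p", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        eeg = synth.SynthEEGParams(**raw.pop("eeg", {}))
        behavior = synth.SynthBehaviorParams(**raw.pop("behavior", {}))
        return cls(eeg=eeg, behavior=behavior, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("eeg", "behavior"):
            d[key] = {str(k): v for k, v in _flatten_params(d[key]).items()}
        return d


def _flatten_params(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = {str(kk): vv for kk, vv in v.items()}
        else:
            out[k] = v
    return out


def fallback_mask(times: np.ndarray, window_s: tuple[float, float],
                  n_channels: int) -> Cluster:
    """All-channel mask over a fixed time window, used for index extraction
    when no cluster reaches significance."""
    ti = np.flatnonzero((times >= window_s[0]) & (times <= window_s[1]))
    return Cluster(channels=np.arange(n_channels), time_indices=ti,
                   mass=np.nan, p_fwe=np.nan)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage at the configured (scaled-down) problem size."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ("schedule", "cohort", "epochs", "segments", "behavior",
                  "stats"), master.spawn(6))}
    report: dict = {"seeds": seeds}
    files = []

    # --- paradigm ---------------------------------------------------------
    schedule = build_schedule(seeds["schedule"], config.n_blocks,
                              config.trials_per_block)
    events = events_dataframe(schedule)
    io.write_events(events, out_dir / "events.tsv")
    files.append("events.tsv")
    halves = condition_halves(schedule)

    cohort = synth.synth_cohort(config.n_subjects, config.eeg,
                                config.behavior, seed=seeds["cohort"])
    rates = spectral.DEFAULT_RATES
    pos = None

    # --- spectral ---------------------------------------------------------
    subj_spec_all = []       # channel-averaged spectra per subject
    subj_maps = {"pair": [], "element": []}
    subj_rate_halves = []    # (2 rates, 3 conds, 2 halves)
    itpc_index = []
    for sim in cohort:
        segs = synth.synth_sequence_segments(schedule, sim.eeg,
                                             seed=sim.seed,
                                             fs=config.analysis_fs_hz)
        spectra = spectral.itpc_spectra(segs, config.analysis_fs_hz, rates,
                                        halves=halves)
        if pos is None:
            pos = spectral_positions()
        subj_spec_all.append(np.mean(
            [spectra[(c, "all")].values.mean(axis=0) for c in
             [c.value for c in CONDITIONS]], axis=0))
        for rate_name, f in (("pair", rates.pair_rate),
                             ("element", rates.element_rate)):
            subj_maps[rate_name].append(
                [spectra[(c.value, "all")].at(f) for c in CONDITIONS])
        rh = np.empty((2, 3, 2))
        for r, f in enumerate((rates.pair_rate, rates.element_rate)):
            for ci, c in enumerate(CONDITIONS):
                for hi, half in enumerate(("first", "second")):
                    rh[r, ci, hi] = spectra[(c.value, half)].at(f).mean()
        subj_rate_halves.append(rh)
        # pair-rate ITPC difference (interval - beat), second half
        itpc_index.append(rh[0, 1, 1] - rh[0, 2, 1])
    adjacency = channel_adjacency(pos)
    report["peak_tests"] = {
        w: spectral.peak_test(np.stack(subj_spec_all), rates.frequencies,
                              rates, w)
        for w in ("element", "pair")}
    report["itpc_anova"] = {}
    for rate_name in ("pair", "element"):
        res = spectral.condition_anova_topo(
            np.array(subj_maps[rate_name]), pos, adjacency,
            n_perm=config.n_perm, fwhm_mm=config.fwhm_mm,
            forming_p=config.forming_p, seed=seeds["stats"])
        report["itpc_anova"][rate_name] = {
            "n_significant_clusters": len(res["clusters"].significant()),
            "posthoc": res["posthoc"],
        }
    report["split_half"] = spectral.split_half_anova(
        np.stack(subj_rate_halves)).to_dict("records")

    # --- ERPs -------------------------------------------------------------
    erps = []
    for sim in cohort:
        epochs = synth.synth_epochs(schedule, sim.eeg, seed=sim.seed + 1,
                                    fs=config.analysis_fs_hz)
        erps.append(erp_stats.build_condition_erps(epochs))
    cells = erp_stats.stack_cohort(erps)
    times = erps[0].times
    t_mm, res_mm = erp_stats.mismatch_test(
        cells, pos, adjacency, n_perm=config.n_perm, fwhm_mm=config.fwhm_mm,
        forming_p=config.forming_p, seed=seeds["stats"])
    t_cg, res_cg = erp_stats.congruence_test(
        cells, pos, adjacency, n_perm=config.n_perm, fwhm_mm=config.fwhm_mm,
        forming_p=config.forming_p, seed=seeds["stats"] + 1)
    _, res_std = erp_stats.standards_control(
        erps, pos, adjacency, n_perm=config.n_perm, fwhm_mm=config.fwhm_mm,
        forming_p=config.forming_p, seed=seeds["stats"] + 2)
    report["erp"] = {name: _cluster_report(res, times) for name, res in
                     (("mismatch", res_mm), ("congruence", res_cg),
                      ("standards_control", res_std))}
    mm_mask = (res_mm.significant() or [fallback_mask(times, (0.173, 0.223),
                                                      cells.shape[-2])])[0]
    cg_mask = (res_cg.significant() or [fallback_mask(times, (0.130, 0.180),
                                                      cells.shape[-2])])[0]
    neural = erp_stats.subject_indices(cells, mm_mask, cg_mask)

    # --- behavior ---------------------------------------------------------
    responses = pd.concat([
        synth.synth_behavior(schedule, sim.behavior, seed=sim.seed + 2,
                             subject=sim.subject)
        for sim in cohort], ignore_index=True)
    responses.to_csv(out_dir / "responses.tsv", sep="\t", index=False,
                     na_rep="n/a")
    files.append("responses.tsv")
    scores = beh.score_and_filter(responses)
    report["behavior"] = {"halves": beh.halves_tests(responses).to_dict("records")}
    for key, value in (("accuracy_anova", "accuracy_pct"),
                       ("rt_anova", "log_mean_rt")):
        try:
            report["behavior"][key] = beh.rm_anova_time(scores, value)
        except ValueError as err:   # tiny schedules can leave empty RT cells
            logger.warning("%s skipped: %s", key, err)
            report["behavior"][key] = {"error": str(err)}

    indices = pd.DataFrame({
        "behavioral_index": beh.behavioral_index(scores).to_numpy(),
        "itpc_index": itpc_index,
        "congruence_index": neural["congruence_index"],
        "mismatch_index": neural["mismatch_index"],
    })
    indices.to_csv(out_dir / "subject_indices.tsv", sep="\t", index=False)
    files.append("subject_indices.tsv")
    if len(indices) >= 5:
        report["brain_behavior"] = beh.brain_behavior(indices)
    else:
        logger.warning("cohort too small for the brain-behavior analysis")
        report["brain_behavior"] = {"skipped": "needs >=5 subjects",
                                    "n_total": int(len(indices))}

    io.write_json(report, out_dir / "report.json")
    files.append("report.json")
    io.write_manifest(out_dir, config.to_dict(), files)
    return report


def spectral_positions():
    from .montage import positions_2d
    return positions_2d()


def _cluster_report(result, times) -> dict:
    out = {"n_permutations": result.n_permutations,
           "forming_threshold": result.forming_threshold, "clusters": []}
    for c in result.clusters[:5]:
        entry = {"n_channels": int(len(c.channels)), "mass": c.mass,
                 "p_fwe": c.p_fwe}
        if c.time_indices is not None:
            w = c.time_window_s(times)
            entry["window_ms"] = [1000 * w[0], 1000 * w[1]]
        out["clusters"].append(entry)
    return out
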