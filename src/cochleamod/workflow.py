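"""End-to-end orchestration: simulate -> preprocess -> specparam -> stats ->
cluster -> report, with a run manifest for reproducibility.

A study run processes a synthetic cohort subject by subject (sessions are
memory-heavy), accumulates per-subject spectral fits, peak validations,
evoked phases and attention modulation indices, computes the group-level
statistics, runs the cluster permutation analyses on a simulated source-power
grid tied to the measured cochlear AMIs, and writes a machine-readable
report.  Every stage's artifacts are checksummed into the manifest; rerunning
an identical configuration reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clus
from . import io, preproc, specparam, stats, synth

EARS = ("left", "right")
CONDITIONS = ("auditory", "visual")


@dataclass(frozen=True)
class PreprocConfig:
    window: tuple[float, float] = (0.25, 1.95)
    band_low: float = 1000.0
    band_high: float = 2000.0
    half_width: float = 30.0
    n_windows: int = 201
    env_sampling_rate: float = 500.0
    highpass_cutoff: float = 500.0
    highpass_order: int = 6
    clip_fraction: float = 0.999
    min_run_ms: float = 2.0
    grid_df: float = 0.25
    mod_freq_range: tuple[float, float] = (1.0, 30.0)
    epoch_duration: float = 3.0


@dataclass(frozen=True)
class SpecparamConfig:
    freq_range: tuple[float, float] = (1.0, 30.0)
    max_peaks: int = 6
    peak_threshold: float = 2.0
    min_peak_height: float = 0.05
    peak_limit: float = 11.0


@dataclass(frozen=True)
class StatsConfig:
    pool_band_range: tuple[float, float] = (1000.0, 2000.0)
    pool_mod_range_left: tuple[float, float] = (3.0, 10.0)
    pool_mod_range_right: tuple[float, float] = (1.0, 10.0)
    fdr_q: float = 0.05
    uniformity_support: tuple[float, float] = (1.0, 11.0)
    run_median_split: bool = True


@dataclass(frozen=True)
class ClusterConfig:
    n_perm: int = 500
    forming_alpha: float = 0.05
    freq_range: tuple[float, float] = (3.0, 25.0)


@dataclass(frozen=True)
class StudyConfig:
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    specparam: SpecparamConfig = field(default_factory=SpecparamConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    save_recordings: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        bad = [k for k in d if k not in {f.name for f in dataclasses.fields(cls)}]
        if bad:
            raise ValueError(f"unknown StudyConfig keys: {bad}")
        sections = {}
        for f_ in dataclasses.fields(cls):
            if f_.name not in d:
                continue
            sub = d[f_.name]
            if f_.name == "save_recordings":
                sections[f_.name] = bool(sub)
                continue
            sub_cls = {"generator": synth.GeneratorConfig, "preproc": PreprocConfig,
                       "specparam": SpecparamConfig, "stats": StatsConfig,
                       "cluster": ClusterConfig}[f_.name]
            names = {sf.name for sf in dataclasses.fields(sub_cls)}
            bad = [k for k in sub if k not in names]
            if bad:
                raise ValueError(f"unknown {f_.name} keys: {bad}")
            sub = {k: (tuple(v) if isinstance(v, list) else v) for k, v in sub.items()}
            if f_.name == "generator" and "rt_params" in sub:
                sub["rt_params"] = synth.RTParams(**sub["rt_params"])
            sections[f_.name] = sub_cls(**sub)
        return cls(**sections)

    def config_hash(self) -> str:
        canon = io.yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class RunManifest:
    config_hash: str
    version: str
    run_dir: str
    stages: list = field(default_factory=list)  # {name, wall_clock_s, checksums}

    def add(self, name: str, wall: float, checksums: dict) -> None:
        self.stages.append({"name": name, "wall_clock_s": round(wall, 3),
                            "checksums": checksums})

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _subject_ear_results(subject, ear, cfg: StudyConfig):
    """All spectra and fits for one subject ear."""
    pp, sp = cfg.preproc, cfg.specparam
    # saturation detection must see the raw recording: high-pass filtering
    # turns a clipped (near-DC) plateau into ordinary in-band signal
    raw = preproc.extract_epochs(subject.recordings[ear], subject.trial_table,
                                 subject.sampling_rate, pp.epoch_duration,
                                 subject.subject_id, ear)
    raw = preproc.reject_saturation(raw, pp.clip_fraction, pp.min_run_ms,
                                    full_scale=cfg.generator.full_scale)
    rec = preproc.highpass_oae(subject.recordings[ear], subject.sampling_rate,
                               pp.highpass_cutoff, pp.highpass_order)
    ep = preproc.extract_epochs(rec, subject.trial_table, subject.sampling_rate,
                                pp.epoch_duration, subject.subject_id, ear)
    ep = ep.subset(raw.trial_index)
    ep.rejected_trials = list(raw.rejected_trials)
    if cfg.stats.run_median_split:
        clean = subject.trial_table.loc[ep.trial_index]
        speed, _ = stats.median_split(clean, group_cols=("condition",))
    out = {"n_rejected": len(ep.rejected_trials),
           "rejections": [(int(i), reason) for i, reason in ep.rejected_trials]}
    for cond in CONDITIONS:
        epc = ep.select(cond)
        if epc.n_trials == 0:
            raise ValueError(f"no clean trials for {subject.subject_id}/{ear}/{cond}")
        bank = preproc.bandpass_bank(epc, pp.band_low, pp.band_high,
                                     pp.half_width, pp.n_windows,
                                     pp.env_sampling_rate)
        spectra = {
            "induced": preproc.induced_mod_spectrum(bank, pp.window, pp.grid_df,
                                                    pp.mod_freq_range),
            "evoked": preproc.evoked_mod_spectrum(bank, pp.window, pp.grid_df,
                                                  pp.mod_freq_range),
        }
        entry = {"spectra": spectra, "fits": {}, "validation": {}}
        for mode, spec in spectra.items():
            fit = specparam.fit_modulation_spectrum(
                spec, freq_range=sp.freq_range, max_peaks=sp.max_peaks,
                peak_threshold=sp.peak_threshold,
                min_peak_height=sp.min_peak_height)
            entry["fits"][mode] = fit
            entry["validation"][mode] = specparam.validate_primary_peak(
                fit, spec.mod_freqs, spec.band_average(), sp.peak_limit)
        evoked_peak = specparam.primary_low_freq_peak(entry["fits"]["evoked"],
                                                      sp.peak_limit)
        if evoked_peak is not None:
            entry["evoked_phase"] = specparam.extract_evoked_phase(
                spectra["evoked"], (pp.band_low, pp.band_high),
                evoked_peak.center_freq)
        if cfg.stats.run_median_split:
            entry["split_spectra"] = {}
            for spd in ("slow", "fast"):
                ids = speed.index[(speed == spd)
                                  & (clean["condition"] == cond)].to_numpy()
                sub_bank = preproc.BandEnvelopeSet(
                    bank.band_centers,
                    bank.data[np.isin(epc.trial_index, ids)],
                    bank.env_sampling_rate, bank.epoch_start)
                entry["split_spectra"][spd] = preproc.induced_mod_spectrum(
                    sub_bank, pp.window, pp.grid_df, pp.mod_freq_range)
        out[cond] = entry
    return out


def _peak_cf(fit, limit):
    p = specparam.primary_low_freq_peak(fit, limit)
    return np.nan if p is None else p.center_freq


def _pool(cfg: StudyConfig, ami_map, ear):
    mod_range = (cfg.stats.pool_mod_range_left if ear == "left"
                 else cfg.stats.pool_mod_range_right)
    return stats.pool_ami(ami_map, cfg.stats.pool_band_range, mod_range)


def _res(r: stats.GroupTestResult) -> dict:
    d = {"statistic": r.statistic, "df": r.df, "p_raw": r.p_raw, "n": r.n,
         "tail": r.tail, "status": r.status}
    if r.p_fdr is not None:
        d["p_fdr"] = r.p_fdr
    return d


def _apply_fdr(results: dict, keys: list, q: float) -> None:
    ok = [k for k in keys if results[k].status == "ok"]
    if not ok:
        return
    p_adj, _ = stats.fdr_correct([results[k].p_raw for k in ok], q)
    for k, p in zip(ok, p_adj):
        results[k].p_fdr = float(p)


def run_study(config: StudyConfig, out_dir) -> RunManifest:
    """Execute the full pipeline; artifacts land under ``out_dir``.

    The directory must not already contain a manifest (one run directory per
    invocation).  Partial failures raise StageError; the manifest written so
    far records the completed stages.
    """
    from . import __version__

    config.generator.validate()
    if config.generator.n_subjects < 1:
        raise ValueError("need at least one subject")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists():
        raise FileExistsError("run directory already holds a manifest; "
                              "use a fresh directory per invocation")
    manifest = RunManifest(config.config_hash(), __version__, str(out))
    io.save_yaml(out / "config.yaml", _listify(config.to_dict()))

    per_subject = []  # nested result records
    tables = {}
    sim_wall = 0.0
    proc_wall = 0.0
    try:
        cohort = synth.iter_cohort(config.generator)
        while True:
            t_sim = time.time()
            subject = next(cohort, None)
            if subject is None:
                break
            tables[subject.subject_id] = subject.trial_table
            if config.save_recordings:
                io.save_recordings(out / f"recordings_{subject.subject_id}.h5",
                                   subject.recordings, subject.sampling_rate)
            sim_wall += time.time() - t_sim
            t_proc = time.time()
            rec = {"subject_id": subject.subject_id, "true_fm": subject.mod_freq}
            for ear in EARS:
                rec[ear] = _subject_ear_results(subject, ear, config)
            per_subject.append(rec)
            proc_wall += time.time() - t_proc
    except Exception as e:  # noqa: BLE001 - stage tagging
        io.save_json(out / "manifest.json", manifest.to_dict())
        raise StageError("simulate/preprocess", e) from e

    # ---- simulate stage artifacts
    sums = {}
    for sid, tab in tables.items():
        p = out / f"trials_{sid}.tsv"
        io.save_trial_table(p, tab)
        sums[p.name] = io.sha256_file(p)
    manifest.add("simulate", sim_wall, sums)

    # ---- preprocess stage artifacts
    spectra_flat = {}
    for rec in per_subject:
        for ear in EARS:
            for cond in CONDITIONS:
                for mode, spec in rec[ear][cond]["spectra"].items():
                    spectra_flat[f"{rec['subject_id']}/{ear}/{cond}/{mode}"] = spec
    spec_path = out / "spectra.h5"
    io.save_spectra(spec_path, spectra_flat)
    rej_rows = [{"subject_id": rec["subject_id"], "ear": ear,
                 "trial": trial, "reason": reason}
                for rec in per_subject for ear in EARS
                for trial, reason in rec[ear]["rejections"]]
    rej_path = out / "rejections.tsv"
    pd.DataFrame(rej_rows, columns=["subject_id", "ear", "trial",
                                    "reason"]).to_csv(rej_path, sep="\t",
                                                      index=False)
    manifest.add("preprocess", proc_wall,
                 {spec_path.name: io.sha256_file(spec_path),
                  rej_path.name: io.sha256_file(rej_path)})

    # ---- specparam stage
    t1 = time.time()
    try:
        fit_rows = []
        for rec in per_subject:
            for ear in EARS:
                for cond in CONDITIONS:
                    e = rec[ear][cond]
                    for mode in ("induced", "evoked"):
                        fit = e["fits"][mode]
                        val = e["validation"][mode]
                        fit_rows.append({
                            "subject_id": rec["subject_id"], "ear": ear,
                            "condition": cond, "mode": mode,
                            "peak_freq": _peak_cf(fit, config.specparam.peak_limit),
                            "slope": fit.exponent, "offset": fit.offset,
                            "n_peaks": len(fit.peaks),
                            "fit_error": fit.fit_error,
                            "dixon_q": val.q_statistic,
                            "dixon_applicable": val.q_applicable,
                            "dixon_significant": val.q_significant,
                        })
        fits = pd.DataFrame(fit_rows)
        fits_path = out / "fits.tsv"
        fits.to_csv(fits_path, sep="\t", index=False, float_format="%.6f")
        manifest.add("specparam", time.time() - t1,
                     {fits_path.name: io.sha256_file(fits_path)})
    except Exception as e:  # noqa: BLE001
        io.save_json(out / "manifest.json", manifest.to_dict())
        raise StageError("specparam", e) from e

    # ---- stats stage
    t2 = time.time()
    try:
        group = _group_stats(config, per_subject, tables, fits)
        stats_path = out / "stats.json"
        io.save_json(stats_path, group)
        manifest.add("stats", time.time() - t2,
                     {stats_path.name: io.sha256_file(stats_path)})
    except Exception as e:  # noqa: BLE001
        io.save_json(out / "manifest.json", manifest.to_dict())
        raise StageError("stats", e) from e

    # ---- cluster stage
    t3 = time.time()
    try:
        cluster_out = _cluster_stage(config, group)
        cl_path = out / "cluster.json"
        io.save_json(cl_path, cluster_out)
        manifest.add("cluster", time.time() - t3,
                     {cl_path.name: io.sha256_file(cl_path)})
    except Exception as e:  # noqa: BLE001
        io.save_json(out / "manifest.json", manifest.to_dict())
        raise StageError("cluster", e) from e

    io.save_json(out / "manifest.json", manifest.to_dict())

    # ---- report stage (reads artifacts back)
    t4 = time.time()
    report = emit_report(out)
    manifest.stages.append({"name": "report", "wall_clock_s": round(time.time() - t4, 3),
                            "checksums": {"report.json": io.sha256_file(out / "report.json")}})
    io.save_json(out / "manifest.json", manifest.to_dict())
    return manifest


def _group_stats(cfg: StudyConfig, per_subject, tables, fits: pd.DataFrame) -> dict:
    q = cfg.stats.fdr_q
    limit = cfg.specparam.peak_limit
    out = {"n_subjects": len(per_subject)}

    # behavioral
    rts = {c: [] for c in CONDITIONS}
    accs = {c: [] for c in CONDITIONS}
    for sid, tab in tables.items():
        for c in CONDITIONS:
            sub = tab[tab["condition"] == c]
            rts[c].append(sub["reaction_time_ms"].mean())
            accs[c].append(sub["accuracy"].mean() * 100)
    out["behavior"] = {
        "rt_mean_ms": {c: float(np.mean(rts[c])) for c in CONDITIONS},
        "rt_sd_ms": {c: float(np.std(rts[c], ddof=1)) for c in CONDITIONS},
        "accuracy_mean_pct": {c: float(np.mean(accs[c])) for c in CONDITIONS},
        "rt_t_test": _res(stats.t_test(rts["auditory"], rts["visual"])),
        "accuracy_t_test": _res(stats.t_test(accs["auditory"], accs["visual"])),
    }

    # peak frequencies & slopes per mode/ear/condition
    descr = {}
    mode_tests = {}
    for mode in ("induced", "evoked"):
        for ear in EARS:
            sel = fits[(fits["mode"] == mode) & (fits["ear"] == ear)]
            piv_pf = sel.pivot(index="subject_id", columns="condition",
                               values="peak_freq")
            piv_sl = sel.pivot(index="subject_id", columns="condition",
                               values="slope")
            for cond in CONDITIONS:
                pf = piv_pf[cond].dropna()
                descr[f"{mode}_{ear}_{cond}"] = {
                    "peak_freq_mean": float(pf.mean()),
                    "peak_freq_sd": float(pf.std(ddof=1)),
                    "slope_mean": float(piv_sl[cond].mean()),
                    "slope_sd": float(piv_sl[cond].std(ddof=1)),
                    "n_with_peak": int(pf.size),
                }
            both = piv_pf.dropna()
            mode_tests[f"{mode}_{ear}_peakfreq"] = stats.t_test(
                both["auditory"], both["visual"])
            mode_tests[f"{mode}_{ear}_slope"] = stats.t_test(
                piv_sl["auditory"], piv_sl["visual"])
    _apply_fdr(mode_tests, list(mode_tests), q)
    out["descriptives"] = descr
    out["condition_tests"] = {k: _res(v) for k, v in mode_tests.items()}

    # induced vs evoked peak frequency (pooled over ears/conditions per subject)
    ind = fits[fits["mode"] == "induced"].groupby("subject_id")["peak_freq"].mean()
    evo = fits[fits["mode"] == "evoked"].groupby("subject_id")["peak_freq"].mean()
    common = ind.index.intersection(evo.index)
    mask = (~ind[common].isna()) & (~evo[common].isna())
    if mask.sum() >= 2:
        out["induced_vs_evoked_freq"] = _res(stats.t_test(
            ind[common][mask], evo[common][mask]))

    # Dixon aggregation
    dixon = {}
    for mode in ("induced", "evoked"):
        sel = fits[fits["mode"] == mode]
        applicable = sel[sel["dixon_applicable"]]
        k = int(applicable["dixon_significant"].sum())
        n = int(len(applicable))
        dixon[mode] = {
            "n_psd": int(len(sel)), "n_tested": n, "n_significant": k,
            "binomial_p": (specparam.binomial_proportion_test(k, n)
                           if n > 0 else None),
        }
    out["dixon"] = dixon

    # uniformity of induced peak frequencies
    ks = {}
    lo, hi = cfg.stats.uniformity_support
    for mode in ("induced", "evoked"):
        for ear in EARS:
            for cond in CONDITIONS:
                sel = fits[(fits["mode"] == mode) & (fits["ear"] == ear)
                           & (fits["condition"] == cond)]
                pf = sel["peak_freq"].dropna().clip(lo, hi)
                if pf.size >= 3:
                    r = stats.ks_uniformity_test(pf, (lo, hi))
                    d = _res(r)
                    d["d_scaled"] = r.d_scaled
                    ks[f"{mode}_{ear}_{cond}"] = d
    out["uniformity"] = ks

    # evoked phase circular tests
    phases = {(rec["subject_id"], ear, cond): rec[ear][cond].get("evoked_phase")
              for rec in per_subject for ear in EARS for cond in CONDITIONS}
    by_ear = {ear: [v for (s, e, c), v in phases.items()
                    if e == ear and v is not None] for ear in EARS}
    by_cond = {cond: [v for (s, e, c), v in phases.items()
                      if c == cond and v is not None] for cond in CONDITIONS}
    circ = {}
    if min(len(v) for v in by_ear.values()) >= 5:
        circ["ear"] = stats.circ_common_median_test(by_ear["left"], by_ear["right"])
    if min(len(v) for v in by_cond.values()) >= 5:
        circ["modality"] = stats.circ_common_median_test(by_cond["auditory"],
                                                         by_cond["visual"])
    _apply_fdr(circ, list(circ), q)
    out["evoked_phase_tests"] = {k: _res(v) for k, v in circ.items()}

    # AMI
    ami_vals = {}  # (mode, ear) -> per-subject pooled AMI
    for mode in ("induced", "evoked"):
        for ear in EARS:
            vals = []
            for rec in per_subject:
                amap = stats.compute_ami(rec[ear]["auditory"]["spectra"][mode],
                                         rec[ear]["visual"]["spectra"][mode],
                                         rec["subject_id"], ear)
                vals.append(_pool(cfg, amap, ear))
            ami_vals[(mode, ear)] = np.asarray(vals)
    ami_tests = {f"{m}_{e}": stats.t_test(ami_vals[(m, e)], tail="greater")
                 for m in ("induced", "evoked") for e in EARS}
    _apply_fdr(ami_tests, [k for k in ami_tests if k.startswith("induced")], q)
    _apply_fdr(ami_tests, [k for k in ami_tests if k.startswith("evoked")], q)
    out["ami"] = {
        "pooled_mean_pct": {f"{m}_{e}": float(ami_vals[(m, e)].mean())
                            for m in ("induced", "evoked") for e in EARS},
        "pooled_se_pct": {f"{m}_{e}": float(ami_vals[(m, e)].std(ddof=1)
                                            / np.sqrt(len(per_subject)))
                          for m in ("induced", "evoked") for e in EARS},
        "t_tests": {k: _res(v) for k, v in ami_tests.items()},
        "interaural": _res(stats.t_test(ami_vals[("induced", "left")],
                                        ami_vals[("induced", "right")])),
        "per_subject_induced": {e: ami_vals[("induced", e)].tolist() for e in EARS},
    }

    # median-split ANOVAs
    if cfg.stats.run_median_split:
        out["median_split"] = _split_stats(cfg, per_subject, q, limit)
    return out


def _split_stats(cfg: StudyConfig, per_subject, q, limit) -> dict:
    factors3 = [("ear", EARS), ("speed", ("slow", "fast")),
                ("condition", CONDITIONS)]
    pf_cells, sl_cells, ami_cells = [], [], []
    for rec in per_subject:
        pf_row, sl_row = [], []
        for ear, spd, cond in ((e, s, c) for e in EARS
                               for s in ("slow", "fast") for c in CONDITIONS):
            spec = rec[ear][cond]["split_spectra"][spd]
            fit = specparam.fit_modulation_spectrum(
                spec, freq_range=cfg.specparam.freq_range,
                max_peaks=cfg.specparam.max_peaks,
                peak_threshold=cfg.specparam.peak_threshold,
                min_peak_height=cfg.specparam.min_peak_height)
            cf = _peak_cf(fit, limit)
            pf_row.append(cf if np.isfinite(cf) else limit / 2)
            sl_row.append(fit.exponent)
        pf_cells.append(pf_row)
        sl_cells.append(sl_row)
        ami_row = []
        for ear in EARS:
            for spd in ("slow", "fast"):
                amap = stats.compute_ami(
                    rec[ear]["auditory"]["split_spectra"][spd],
                    rec[ear]["visual"]["split_spectra"][spd],
                    rec["subject_id"], ear)
                ami_row.append(_pool(cfg, amap, ear))
        ami_cells.append(ami_row)

    out = {
        "anova_peak_freq": {k: _res(v) for k, v in
                            stats.rm_anova(np.asarray(pf_cells), factors3).items()},
        "anova_slope": {k: _res(v) for k, v in
                        stats.rm_anova(np.asarray(sl_cells), factors3).items()},
        "anova_ami": {k: _res(v) for k, v in
                      stats.rm_anova(np.asarray(ami_cells),
                                     [("ear", EARS),
                                      ("speed", ("slow", "fast"))]).items()},
    }
    ami_arr = np.asarray(ami_cells)  # columns: left/slow, left/fast, right/slow, right/fast
    cols = {("left", "slow"): 0, ("left", "fast"): 1,
            ("right", "slow"): 2, ("right", "fast"): 3}
    tests = {f"{ear}_{spd}": stats.t_test(ami_arr[:, i], tail="greater")
             for (ear, spd), i in cols.items()}
    _apply_fdr(tests, list(tests), q)
    out["split_ami_t_tests"] = {k: _res(v) for k, v in tests.items()}
    return out


def _cluster_stage(cfg: StudyConfig, group: dict) -> dict:
    gen = cfg.generator
    rng = np.random.default_rng(np.random.SeedSequence([gen.seed, 2 ** 20]))
    ooa = {e: np.asarray(group["ami"]["per_subject_induced"][e]) for e in EARS}
    grid = synth.simulate_brain_power(gen, ooa["right"], rng)
    lo, hi = cfg.cluster.freq_range
    fsel = (grid.freqs >= lo) & (grid.freqs <= hi)
    power = grid.power[:, :, fsel, :]
    freqs = grid.freqs[fsel]
    adj = clus.lattice_adjacency(gen.grid_shape)
    seed_pool = np.random.SeedSequence([gen.seed, 2 ** 21]).generate_state(4)

    cond_res = clus.condition_cluster_test(power, adj, cfg.cluster.n_perm,
                                           cfg.cluster.forming_alpha,
                                           int(seed_pool[0]), freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        brain_ami = ((power[..., 0] - power[..., 1])
                     / (power[..., 0] + power[..., 1]) * 100.0)
    out = {"condition": _cluster_summary(cond_res, freqs)}
    for i, ear in enumerate(EARS):
        res = clus.correlation_cluster_test(brain_ami, ooa[ear], adj,
                                            cfg.cluster.n_perm,
                                            cfg.cluster.forming_alpha,
                                            int(seed_pool[1 + i]), freqs)
        out[f"correlation_{ear}"] = _cluster_summary(res, freqs)
    return out


def _cluster_summary(res, freqs) -> dict:
    clusters = []
    for c in res.clusters[:10]:
        profile = np.zeros(freqs.size, dtype=int)
        for _, f in c.cells:
            profile[f] += 1
        clusters.append({"size": int(len(c.cells)), "mass": c.mass,
                         "sign": c.sign, "p_mc": c.p_mc,
                         "freq_profile": profile.tolist()})
    return {"n_clusters": len(res.clusters), "min_p": res.min_p(),
            "freqs_hz": freqs.tolist(), "clusters": clusters,
            "n_permutations": res.n_permutations}


def emit_report(run_dir) -> dict:
    """Compose the run's report from stage artifacts.

    Machine-readable JSON plus a short human-readable summary; missing stage
    outputs become explicit "stage absent" entries.
    """
    run = Path(run_dir)
    report = {}
    for name, fname in (("stats", "stats.json"), ("cluster", "cluster.json")):
        path = run / fname
        report[name] = io.load_json(path) if path.exists() else "stage absent"
    fits_path = run / "fits.tsv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path, sep="\t")
        report["n_spectra_fit"] = int(len(fits))
    else:
        report["specparam"] = "stage absent"
    io.save_json(run / "report.json", report)
    (run / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = ["cochleamod study report", "=" * 23]
    st = report.get("stats")
    if isinstance(st, dict):
        lines.append(f"subjects: {st['n_subjects']}")
        b = st["behavior"]
        lines.append("reaction time (ms): "
                     + ", ".join(f"{c} {b['rt_mean_ms'][c]:.1f}" for c in CONDITIONS)
                     + f"; paired t p={b['rt_t_test']['p_raw']:.4g}")
        for key, d in st["descriptives"].items():
            lines.append(f"{key}: peak {d['peak_freq_mean']:.2f} Hz "
                         f"(SD {d['peak_freq_sd']:.2f}), slope {d['slope_mean']:.3f}")
        for mode, d in st["dixon"].items():
            lines.append(f"dixon {mode}: {d['n_significant']}/{d['n_tested']} "
                         f"significant (binomial p={d['binomial_p']:.3g})")
        for k, d in st["ami"]["t_tests"].items():
            lines.append(f"AMI {k}: mean {st['ami']['pooled_mean_pct'][k]:.3f}% "
                         f"t={d['statistic']:.3f} p_fdr={d.get('p_fdr', d['p_raw']):.4g}")
    cl = report.get("cluster")
    if isinstance(cl, dict):
        for k, d in cl.items():
            lines.append(f"cluster {k}: {d['n_clusters']} clusters, min p={d['min_p']:.4g}")
    return "\n".join(lines) + "\n"
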