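"""End-to-end orchestration: simulate -> behavior -> preprocess ->
spectral/connectivity -> statistics, with seeded determinism and a report
bundle of tidy tables plus a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import hit_rate, score_session, summarize_behavior, write_trial_table
from .connectivity import (DEFAULT_WINDOWS, default_te_delay, interareal_plv,
                           pac_nm, phase_te)
from .containers import FISSURE, HILUS
from .preprocess import (build_filter_bank, decompose, interpolate_stimulus_artifact,
                         reject_artifact_trials)
from .spectral import amplitude_tfr, itc
from .stats import (cluster_permutation, equalize_trials, pac_group_test,
                    pte_shuffle_test)
from .synthetic import SimConfig, read_experiment, simulate_experiment

log = logging.getLogger("tebc")

#: named rhythm bands (Hz) as used in the group-level analyses
NAMED_BANDS = {"theta": (4.0, 6.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0),
               "gamma": (30.0, 40.0), "high_gamma": (50.0, 100.0)}


@dataclass
class RunConfig:
    sim: SimConfig = None
    data_path: str = None            # HDF5 container; overrides sim when set
    f_min: float = 3.0
    f_max: float = 100.0
    n_bands: int = 20
    named_bands: dict = field(default_factory=lambda: dict(NAMED_BANDS))
    analysis_window: tuple = (-0.6, 0.6)
    baseline: tuple = (-0.6, -0.1)
    roi_windows: tuple = DEFAULT_WINDOWS
    contrasts: tuple = ("cr", "learning")
    cluster_n_perm: int = 1000
    cluster_t_alpha: float = 0.025
    cluster_alpha: float = 0.05
    artifact_cutoff_uv: float = 1500.0
    min_condition_trials: int = 2
    run_plv: bool = False
    run_pac: bool = False
    run_te: bool = False
    plv_shuffles: int = 100
    pac_lf_hz: float = 9.0
    pac_ratios: tuple = tuple(range(2, 10))
    te_bins: int = 8
    te_shuffles: int = 200
    te_freq_hz: float = 9.0
    te_window: tuple = (0.0, 0.5)
    seed: int = 0
    out_dir: str = None

    def __post_init__(self):
        if self.sim is None and self.data_path is None:
            self.sim = SimConfig()
        if self.sim is not None:
            ep = self.sim.epoch
            for w in (self.analysis_window, self.baseline, *self.roi_windows):
                if w[0] < ep[0] - 1e-9 or w[1] > ep[1] + 1e-9:
                    raise ValueError(f"window {w} outside epoch {ep}")

    def to_dict(self) -> dict:
        # out_dir is a run location, not part of the analysis identity
        d = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim"):
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("analysis_window", "baseline", "contrasts", "pac_ratios",
                    "te_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("roi_windows") is not None:
            d["roi_windows"] = tuple(tuple(w) for w in d["roi_windows"])
        return cls(**d)


def rank_sessions_by_hr(trial_tables: pd.DataFrame) -> pd.DataFrame:
    """Per-animal lowest/highest %HR session labels.

    Ties are broken toward the earlier session for the lowest and the later
    session for the highest.
    """
    rows = []
    for rat, df in trial_tables.groupby("rat"):
        hr = (df[~df["artifact"]].groupby("session")["cr"].mean()
              .sort_index())
        if len(hr) < 2:
            raise ValueError("need >= 2 sessions per animal")
        v = hr.to_numpy()
        lowest = hr.index[int(np.argmin(v))]
        highest = hr.index[len(v) - 1 - int(np.argmax(v[::-1]))]
        rows.append({"rat": rat, "lowest": lowest, "highest": highest,
                     "hr_lowest": hr[lowest], "hr_highest": hr[highest]})
    return pd.DataFrame(rows).set_index("rat")


# ---------------------------------------------------------------------------
# map computation
# ---------------------------------------------------------------------------

def _condition_maps(tfrs, trials_in_tfr, cond_trials, cfg):
    """Amplitude (baseline-corrected) and raw ITC maps for a trial subset.

    ``trials_in_tfr`` maps original trial ids to TFR trial-axis positions.
    """
    pos = np.asarray([trials_in_tfr[t] for t in cond_trials])
    out = {}
    for role, tfr in tfrs.items():
        sub = tfr.select_trials(pos)
        amp = amplitude_tfr(sub, cfg.analysis_window, cfg.baseline)
        coh = itc(sub, cfg.analysis_window, baseline=cfg.baseline)
        out[role] = {"amplitude": amp.corrected, "itc": coh.raw,
                     "itc_corrected": coh.corrected,
                     "freqs": amp.freqs, "times": amp.times}
    return out


def preprocess_session(rec, cfg):
    """Artifact rejection + stimulus-artifact interpolation (in place)."""
    reject_artifact_trials(rec, cfg.artifact_cutoff_uv)
    idx = [rec.time_index(rec.events["cs_onset"]),
           rec.time_index(rec.events["cs_offset"])]
    rec.lfp = interpolate_stimulus_artifact(rec.lfp, rec.fs, idx)
    return rec


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle and, when
    ``config.out_dir`` is set, writes CSV/JSON outputs there.

    Every stochastic step draws from streams spawned off ``config.seed``, so
    an identical configuration yields a byte-identical bundle.
    """
    master = np.random.SeedSequence(config.seed)
    s_eq, s_cluster, s_conn = [np.random.default_rng(s) for s in master.spawn(3)]
    bundle = {"config": config}

    stage = "simulate"
    try:
        if config.data_path is not None:
            sessions = read_experiment(config.data_path)
            ground_truth = None
        else:
            sessions, ground_truth = simulate_experiment(config.sim, config.seed)
        bundle["ground_truth"] = ground_truth

        stage = "preprocess"
        for rec in sessions.values():
            preprocess_session(rec, config)

        stage = "behavior"
        tables = [score_session(rec) for rec in sessions.values()]
        trial_table = pd.concat(tables, ignore_index=True)
        behavior = summarize_behavior(trial_table)
        bundle["trial_table"] = trial_table
        bundle["behavior"] = behavior

        stage = "decompose"
        fs = next(iter(sessions.values())).fs
        bank = build_filter_bank(config.f_min, config.f_max, config.n_bands,
                                 fs=fs)
        bundle["bank_freqs"] = bank.freqs
        rats = sorted({k[0] for k in sessions})
        per_session = {}
        conn_acc = {"plv": [], "pac_post": [], "pac_pre": [], "dte": []}
        for key, rec in sorted(sessions.items()):
            valid = rec.valid_trials()
            tfrs = decompose(rec, bank, trials=valid)
            trials_in_tfr = {t: i for i, t in enumerate(valid)}
            tab = trial_table[(trial_table["rat"] == key[0])
                              & (trial_table["session"] == key[1])]
            cr_ids = tab.loc[tab["cr"] & ~tab["artifact"], "trial"].to_numpy()
            nocr_ids = tab.loc[~tab["cr"] & ~tab["artifact"], "trial"].to_numpy()
            entry = {"hr": hit_rate(tab), "n_valid": valid.size}
            entry["all"] = _condition_maps(tfrs, trials_in_tfr, valid, config)
            if (cr_ids.size >= config.min_condition_trials
                    and nocr_ids.size >= config.min_condition_trials):
                a, b = equalize_trials(cr_ids, nocr_ids, s_eq)
                entry["cr"] = _condition_maps(tfrs, trials_in_tfr, a, config)
                entry["nocr"] = _condition_maps(tfrs, trials_in_tfr, b, config)
            per_session[key] = entry

            if config.run_plv or config.run_pac or config.run_te:
                _accumulate_connectivity(conn_acc, tfrs, bank, rec, config,
                                         key, s_conn)
        bundle["per_session"] = per_session

        stage = "contrasts"
        contrasts = {}
        if "cr" in config.contrasts:
            contrasts["cr"] = _cr_contrast(per_session, rats, config, s_cluster)
        if "learning" in config.contrasts:
            ranks = rank_sessions_by_hr(trial_table)
            bundle["session_ranks"] = ranks
            contrasts["learning"] = _learning_contrast(per_session, rats, ranks,
                                                      config, s_cluster)
        bundle["contrasts"] = contrasts

        stage = "connectivity"
        if config.run_pac and conn_acc["pac_post"]:
            post = np.stack(conn_acc["pac_post"])
            pre = np.stack(conn_acc["pac_pre"])
            bundle["pac"] = {"post": post, "pre": pre,
                             "test": pac_group_test(post, pre)}
        if config.run_plv and conn_acc["plv"]:
            bundle["plv"] = pd.concat(conn_acc["plv"], ignore_index=True)
        if config.run_te and conn_acc["dte"]:
            bundle["dte"] = pd.concat(conn_acc["dte"], ignore_index=True)
    except Exception as exc:  # tag the failing stage, keep partial outputs
        exc.args = (f"[stage {stage}] {exc}",) + exc.args[1:]
        raise

    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def _accumulate_connectivity(acc, tfrs, bank, rec, config, key, rng):
    band = bank.nearest_band(config.te_freq_hz)
    if config.run_plv:
        plv = interareal_plv(tfrs[HILUS], tfrs[FISSURE],
                             n_shuffles=config.plv_shuffles, rng=rng)
        sl = tfrs[HILUS].time_slice(config.te_window)
        df = pd.DataFrame({
            "rat": key[0], "session": key[1], "band_hz": bank.freqs,
            "plv_raw": plv.raw[:, sl].mean(axis=1),
            "plv_norm": plv.normalized[:, sl].mean(axis=1)})
        acc["plv"].append(df)
    if config.run_pac:
        lf_band = bank.nearest_band(config.pac_lf_hz)
        mat = pac_nm(tfrs, bank, [lf_band], config.pac_ratios,
                     config.roi_windows)
        acc["pac_post"].append(mat.post[0])
        acc["pac_pre"].append(mat.pre[0])
        acc.setdefault("pac_meta", mat)
    if config.run_te:
        px = np.angle(tfrs[HILUS].data[band])
        py = np.angle(tfrs[FISSURE].data[band])
        delay = default_te_delay(rec.fs, bank.freqs[band])
        res = pte_shuffle_test([(px, py)], [delay], n_bins=config.te_bins,
                               n_shuffles=config.te_shuffles, rng=rng,
                               fs=rec.fs, epoch=rec.epoch,
                               window=config.te_window)
        acc["dte"].append(pd.DataFrame({
            "rat": [key[0]], "session": [key[1]],
            "band_hz": [bank.freqs[band]], "dte_bits": res.dte,
            "p": res.p, "significant": res.mask}))


def _stack_maps(maps_per_rat):
    return np.stack(maps_per_rat)


def _cr_contrast(per_session, rats, config, rng):
    """Per-animal CR minus no-CR maps (sessions averaged), cluster-tested."""
    out = {}
    for role in (FISSURE, HILUS):
        for metric in ("amplitude", "itc"):
            a_maps, b_maps = [], []
            for rat in rats:
                a_sess = [e["cr"][role][metric] for k, e in per_session.items()
                          if k[0] == rat and "cr" in e]
                b_sess = [e["nocr"][role][metric] for k, e in per_session.items()
                          if k[0] == rat and "nocr" in e]
                if not a_sess:
                    continue
                a_maps.append(np.mean(a_sess, axis=0))
                b_maps.append(np.mean(b_sess, axis=0))
            if len(a_maps) < 2:
                log.warning("cr contrast (%s/%s): <2 animals with both "
                            "conditions; skipped", role, metric)
                continue
            out[(role, metric)] = cluster_permutation(
                _stack_maps(a_maps), _stack_maps(b_maps),
                t_alpha=config.cluster_t_alpha, n_perm=config.cluster_n_perm,
                alpha=config.cluster_alpha, rng=rng)
    return out


def _learning_contrast(per_session, rats, ranks, config, rng):
    """Highest minus lowest %HR session maps per animal, cluster-tested."""
    out = {}
    for role in (FISSURE, HILUS):
        for metric in ("amplitude", "itc"):
            a_maps, b_maps = [], []
            for rat in rats:
                hi = per_session[(rat, ranks.loc[rat, "highest"])]
                lo = per_session[(rat, ranks.loc[rat, "lowest"])]
                a_maps.append(hi["all"][role][metric])
                b_maps.append(lo["all"][role][metric])
            out[(role, metric)] = cluster_permutation(
                _stack_maps(a_maps), _stack_maps(b_maps),
                t_alpha=config.cluster_t_alpha, n_perm=config.cluster_n_perm,
                alpha=config.cluster_alpha, rng=rng)
    return out


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _config_hash(config: RunConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the report bundle as deterministic CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = bundle["config"]
    fmt = "%.10g"

    write_trial_table(bundle["trial_table"], out / "trial_table.csv")
    bundle["behavior"]["hr"].to_csv(out / "hit_rates.csv", float_format=fmt)
    if "session_ranks" in bundle:
        bundle["session_ranks"].to_csv(out / "session_ranks.csv",
                                       float_format=fmt)
    for name, contrast in bundle.get("contrasts", {}).items():
        frames = []
        for (role, metric), res in contrast.items():
            df = res.to_frame()
            df.insert(0, "metric", metric)
            df.insert(0, "channel", role)
            frames.append(df)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"clusters_{name}.csv", index=False, float_format=fmt)
    if "plv" in bundle:
        bundle["plv"].to_csv(out / "plv.csv", index=False, float_format=fmt)
    if "dte" in bundle:
        bundle["dte"].to_csv(out / "dte.csv", index=False, float_format=fmt)
    if "pac" in bundle:
        test = bundle["pac"]["test"]
        np.savetxt(out / "pac_t.csv", test.t.reshape(test.t.shape[0], -1),
                   delimiter=",", fmt=fmt)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "config": config.to_dict(),
        "versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _library_versions() -> dict:
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}
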