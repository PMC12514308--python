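"""End-to-end orchestration: simulate a cohort, preprocess, extract
ERP/ERSP features, run the group statistics, and estimate per-subject
directed connectivity with surrogate significance.

All stages are driven by a single :class:`PipelineConfig` (TOML-loadable)
whose defaults follow the recording protocol: 3 kHz sampling, 0.1-45 Hz
Kaiser FIR (ripple 1e-3, 0.2 Hz transition), 500 microvolt delta criterion,
nMVAR order 8 with 10 hidden units and 100 surrogates.  The ``smoke``
profile scales everything to desk size (600 Hz, 2 subjects per group,
20 surrogates) without changing any algorithm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import io as io_mod
from . import ncreann as nc_mod
from . import preprocess as pre_mod
from . import stats as stats_mod
from . import synth as synth_mod
from . import tfr as tfr_mod

__all__ = ["PipelineConfig", "run_pipeline", "bandpass_contrast"]

log = logging.getLogger("oddconn")

BAND_RANGES = {
    "low_beta": (12.0, 15.0),
    "mid_beta": (15.0, 18.0),
    "high_beta": (18.0, 30.0),
}


@dataclass
class SynthConfig:
    fs: float = 3000.0
    n_per_group: int = 10
    n_blocks: int = 6
    block_duration: float = 300.0
    isi: float = 1.0
    tone_duration: float = 0.05
    deviant_fraction: float = 0.13
    artifact_fraction: float = 0.01
    noise_scale: float = 1.0


@dataclass
class PreprocessConfig:
    low: float = 0.1
    high: float = 45.0
    ripple: float = 0.001
    transition_width: float = 0.2
    delta_criterion: float = 500.0
    bad_channel_fraction: float = 0.5


@dataclass
class FeatureConfig:
    window: tuple[float, float] = (-100.0, 700.0)
    baseline: tuple[float, float] = (-100.0, 0.0)
    ersp_window_samples: int = 400
    ersp_pad_ratio: int = 64
    ersp_n_times: int = 200


@dataclass
class NcreannPipelineConfig:
    p: int = 8
    hidden: int = 10
    momentum: float = 0.9
    eta0: float = 0.001
    max_epochs: int = 200
    patience: int = 6
    n_reps: int = 10
    n_surrogates: int = 100
    surrogate_n_reps: int = 1
    surrogate_max_epochs: int | None = None
    band: str = "broadband"
    min_channels: int = 8

    def net_config(self) -> nc_mod.NetConfig:
        return nc_mod.NetConfig(
            hidden=self.hidden, momentum=self.momentum, eta0=self.eta0,
            max_epochs=self.max_epochs, patience=self.patience,
            n_reps=self.n_reps,
        )

    def surrogate_config(self) -> nc_mod.NetConfig:
        cfg = self.net_config()
        if self.surrogate_max_epochs is not None:
            cfg = dataclasses.replace(cfg, max_epochs=self.surrogate_max_epochs)
        return cfg


@dataclass
class StatsConfig:
    alpha: float = 0.05
    fdr: bool = True


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ncreann: NcreannPipelineConfig = field(default_factory=NcreannPipelineConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def smoke(cls) -> "PipelineConfig":
        """Desk-scale profile: identical algorithms, reduced sizes."""
        return cls(
            synth=SynthConfig(fs=600.0, n_per_group=2, n_blocks=2),
            features=FeatureConfig(
                ersp_window_samples=80, ersp_pad_ratio=8, ersp_n_times=60
            ),
            ncreann=NcreannPipelineConfig(
                max_epochs=30, n_reps=2, n_surrogates=20,
                surrogate_max_epochs=15,
            ),
        )

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as f:
            raw = tomllib.load(f)
        cfg = cls()
        sections = {
            "synth": cfg.synth,
            "preprocess": cfg.preprocess,
            "features": cfg.features,
            "ncreann": cfg.ncreann,
            "stats": cfg.stats,
        }
        for name, section in sections.items():
            for key, val in raw.get(name, {}).items():
                if not hasattr(section, key):
                    raise ValueError(f"unknown config key [{name}] {key}")
                cur = getattr(section, key)
                if isinstance(cur, tuple):
                    val = tuple(val)
                setattr(section, key, val)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def simulate_cohort(config: PipelineConfig, seed: int):
    """One recording per subject x treatment, plus the alcohol cohort's
    drinking table."""
    sc = config.synth
    ss = np.random.SeedSequence(seed)
    recordings = {}
    for group in ("control", "alcohol"):
        for s in range(sc.n_per_group):
            subject = f"{group}{s:02d}"
            for treatment in ("pre", "post"):
                child = ss.spawn(1)[0]
                sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
                events = synth_mod.make_stimulus_sequence(
                    n_blocks=sc.n_blocks,
                    block_duration=sc.block_duration,
                    isi=sc.isi,
                    tone_duration=sc.tone_duration,
                    deviant_fraction=sc.deviant_fraction,
                    seed=sub_seed,
                )
                rng = np.random.default_rng(sub_seed + 1)
                n_art = int(round(sc.artifact_fraction * len(events)))
                artifacts = tuple(
                    sorted(rng.choice(len(events), size=n_art, replace=False))
                ) if n_art else ()
                rec = synth_mod.simulate_session(
                    events,
                    preset=f"{group}_{treatment}",
                    fs=sc.fs,
                    seed=sub_seed + 2,
                    noise_scale=sc.noise_scale,
                    artifact_trials=artifacts,
                    subject=subject,
                )
                recordings[(subject, treatment)] = rec
    drink_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
    drinking = synth_mod.simulate_drinking(
        n_rats=sc.n_per_group, seed=drink_seed
    )
    drinking["rat"] = drinking["rat"].str.replace("rat", "alcohol")
    return recordings, drinking


def preprocess_recording(
    rec: synth_mod.Recording, config: PipelineConfig, kernel=None
) -> pre_mod.EpochSet:
    pc = config.preprocess
    if kernel is None:
        kernel = pre_mod.design_bandpass_fir(
            rec.fs, pc.low, pc.high, pc.ripple, pc.transition_width
        )
    filtered = pre_mod.apply_filter(rec, kernel)
    epochs = pre_mod.epoch_and_baseline(
        filtered, config.features.window, config.features.baseline
    )
    return pre_mod.reject_artifacts(
        epochs, pc.delta_criterion, pc.bad_channel_fraction
    )


def extract_features(epochs: pre_mod.EpochSet, config: PipelineConfig) -> pd.DataFrame:
    """Tidy feature rows for one session: component latencies, peak-to-peak
    amplitudes, and per-band ERSP maxima of the deviant-minus-standard
    contrast."""
    fc = config.features
    _, _, diff = erp_mod.average_and_difference(epochs)
    peaks = erp_mod.peak_to_peak(erp_mod.detect_peaks(diff))
    maps = tfr_mod.ersp_contrast(
        epochs,
        window_samples=fc.ersp_window_samples,
        pad_ratio=fc.ersp_pad_ratio,
        n_times=fc.ersp_n_times,
    )
    bands = tfr_mod.band_features(maps["contrast"])

    rows = []
    meta = epochs.meta
    base = {
        "subject": meta.get("subject"),
        "group": meta.get("group"),
        "treatment": meta.get("treatment"),
    }
    for _, r in peaks.iterrows():
        if r["component"] in erp_mod.COMPONENT_WINDOWS:
            rows.append(
                {**base, "channel": r["channel"],
                 "measure": f"latency_{r['component']}", "value": r["latency"]}
            )
            rows.append(
                {**base, "channel": r["channel"],
                 "measure": f"amplitude_{r['component']}", "value": r["amplitude"]}
            )
        else:
            rows.append(
                {**base, "channel": r["channel"],
                 "measure": f"p2p_{r['component']}", "value": r["amplitude"]}
            )
    for _, r in bands.iterrows():
        for what, val in (
            ("max", r["max_db"]), ("latency", r["latency"]), ("freq", r["frequency"])
        ):
            rows.append(
                {**base, "channel": r["channel"],
                 "measure": f"ersp_{what}_{r['band']}", "value": val}
            )
    df = pd.DataFrame(rows)
    # bad channels are unobserved -> missing, to be imputed across subjects
    if epochs.bad_channels:
        df.loc[df["channel"].isin(epochs.bad_channels), "value"] = np.nan
    return df


def impute_feature_table(features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Impute missing channel cells measure-wise across subjects."""
    if not features["value"].isna().any():
        return features.copy()
    wide = features.pivot_table(
        index=["subject", "group", "treatment"],
        columns=["measure", "channel"],
        values="value",
        dropna=False,
    )
    wide.columns = [f"{m}|{c}" for m, c in wide.columns]
    filled = pre_mod.impute_features(wide.reset_index(drop=True), seed=seed)
    filled.index = wide.index
    out = filled.stack().reset_index()
    out.columns = ["subject", "group", "treatment", "key", "value"]
    out[["measure", "channel"]] = out["key"].str.split("|", expand=True)
    return out.drop(columns="key")[
        ["subject", "group", "treatment", "channel", "measure", "value"]
    ]


def bandpass_contrast(
    contrast: nc_mod.ContrastSet, low: float, high: float,
    transition_width: float = 4.0, ripple: float = 0.01,
) -> nc_mod.ContrastSet:
    """Band-restrict the contrast trials (e.g. to a beta subrange) before
    connectivity estimation.  The FIR is applied to the concatenated
    per-channel series so the kernel fits comfortably."""
    from scipy.signal import oaconvolve

    n_trials, M, T = contrast.data.shape
    kernel = pre_mod.design_bandpass_fir(
        contrast.fs, low, high, ripple=ripple, transition_width=transition_width
    )
    concat = contrast.data.transpose(1, 0, 2).reshape(M, n_trials * T)
    filt = oaconvolve(concat, kernel.taps[None, :], axes=1, mode="same")
    data = filt.reshape(M, n_trials, T).transpose(1, 0, 2)
    return contrast.copy_with(data=data)


def connectivity_stage(
    epoch_sets: dict, config: PipelineConfig, seed: int
) -> tuple[dict, pd.DataFrame, list]:
    """Per-subject connectivity on the post-stimulation sessions plus the
    Mann-Whitney group comparison per connection."""
    ncfg = config.ncreann
    results = {}
    excluded = []
    ss = np.random.SeedSequence(seed)
    for (subject, treatment), epochs in sorted(epoch_sets.items()):
        if treatment != "post":
            continue
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        try:
            if ncfg.band != "broadband":
                band = BAND_RANGES[ncfg.band]
                for bad in epochs.bad_channels:
                    epochs = pre_mod.interpolate_channel(epochs, bad)
                contrast = nc_mod.contrast_trials(epochs)
                contrast = bandpass_contrast(contrast, *band)
                res = nc_mod.surrogate_test(
                    contrast, p=ncfg.p, config=ncfg.net_config(),
                    n_surrogates=ncfg.n_surrogates, seed=sub_seed,
                    alpha=config.stats.alpha,
                    surrogate_config=ncfg.surrogate_config(),
                    surrogate_n_reps=ncfg.surrogate_n_reps,
                )
            else:
                res = nc_mod.estimate_connectivity(
                    epochs, p=ncfg.p, config=ncfg.net_config(),
                    n_surrogates=ncfg.n_surrogates, seed=sub_seed,
                    alpha=config.stats.alpha,
                    min_channels=ncfg.min_channels,
                    surrogate_config=ncfg.surrogate_config(),
                    surrogate_n_reps=ncfg.surrogate_n_reps,
                )
            results[subject] = res
        except nc_mod.SubjectExcluded as e:
            log.warning("subject %s excluded: insufficient channels (%s)", subject, e)
            excluded.append({"subject": subject, "reason": "insufficient channels"})

    rows = []
    groups = sorted({s.rstrip("0123456789") for s in results})
    if len(groups) == 2 and all(
        sum(s.startswith(g) for s in results) >= 2 for g in groups
    ):
        labels = next(iter(results.values())).channel_labels
        M = len(labels)
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                for kind in ("lc", "nc"):
                    vals = {
                        g: [
                            getattr(results[s], kind)[i, j]
                            for s in results
                            if s.startswith(g)
                        ]
                        for g in groups
                    }
                    u, pval, r = stats_mod.mann_whitney_effect(
                        vals[groups[0]], vals[groups[1]]
                    )
                    rows.append(
                        {
                            "from": labels[i], "to": labels[j],
                            "kind": kind.upper(), "U": u, "p": pval,
                            "effect_size": r,
                        }
                    )
    comparison = pd.DataFrame(rows)
    if len(comparison) and config.stats.fdr:
        comparison["p_fdr"] = stats_mod.fdr_adjust(comparison["p"].to_numpy())
    return results, comparison, excluded


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig, seed: int, outdir: str | Path,
    save_recordings: bool = False,
) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns a dict with the in-memory results (feature table, ANOVA tables,
    connectivity comparison, drinking summaries, run log).
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        recordings, drinking = simulate_cohort(config, seed)
        if save_recordings:
            (outdir / "recordings").mkdir(exist_ok=True)
            for (subject, treatment), rec in recordings.items():
                io_mod.save_recording(
                    rec, outdir / "recordings" / f"{subject}_{treatment}.h5"
                )

        stage = "preprocess"
        kernel = pre_mod.design_bandpass_fir(
            config.synth.fs, config.preprocess.low, config.preprocess.high,
            config.preprocess.ripple, config.preprocess.transition_width,
        )
        epoch_sets = {}
        for key, rec in sorted(recordings.items()):
            epoch_sets[key] = preprocess_recording(rec, config, kernel)

        stage = "features"
        feats = pd.concat(
            [extract_features(ep, config) for ep in epoch_sets.values()],
            ignore_index=True,
        ).sort_values(
            ["measure", "subject", "treatment", "channel"]
        ).reset_index(drop=True)
        feats.to_csv(outdir / "features.csv", index=False)
        feats_imp = impute_feature_table(feats, seed=seed)
        feats_imp.to_csv(outdir / "features_imputed.csv", index=False)

        stage = "stats"
        anova_rows = []
        for measure, df_m in feats_imp.groupby("measure"):
            tab = stats_mod.rm_anova(df_m)
            tab.insert(0, "measure", measure)
            anova_rows.append(tab)
        anova = pd.concat(anova_rows, ignore_index=True)
        if config.stats.fdr:
            anova["p_fdr"] = np.nan
            for effect, idx in anova.groupby("effect").groups.items():
                anova.loc[idx, "p_fdr"] = stats_mod.fdr_adjust(
                    anova.loc[idx, "p"].to_numpy()
                )
        anova.to_csv(outdir / "anova.csv", index=False)

        paired_rows = []
        for (measure, group), df_m in feats_imp.groupby(["measure", "group"]):
            wide = df_m.pivot_table(
                index="subject", columns=["treatment", "channel"], values="value"
            )
            if wide.shape[0] < 3:
                log.info(
                    "skipping paired t for %s/%s: fewer than 3 subjects",
                    measure, group,
                )
                continue
            chans = sorted(df_m["channel"].unique())
            pre = wide["pre"][chans].to_numpy()
            post = wide["post"][chans].to_numpy()
            tt = stats_mod.paired_t_by_channel(pre, post)
            tt["channel"] = chans
            tt.insert(0, "group", group)
            tt.insert(0, "measure", measure)
            paired_rows.append(tt)
        paired = (
            pd.concat(paired_rows, ignore_index=True)
            if paired_rows
            else pd.DataFrame(
                columns=["measure", "group", "channel", "t", "p", "zero_variance", "p_fdr"]
            )
        )
        paired.to_csv(outdir / "paired_t.csv", index=False)

        stage = "connectivity"
        conn_results, conn_comparison, excluded = connectivity_stage(
            epoch_sets, config, seed + 1
        )
        for subject, res in conn_results.items():
            io_mod.save_connectivity(res, outdir / "connectivity", prefix=subject)
        conn_comparison.to_csv(outdir / "connectivity_group_comparison.csv", index=False)

        stage = "drinking"
        drinking.to_csv(outdir / "drinking.csv", index=False)
        drink_res = stats_mod.drinking_measures(drinking)
        drink_res.per_rat.to_csv(outdir / "drinking_measures.csv", index=False)
        drink_res.anova.to_csv(outdir / "drinking_anova.csv", index=False)
        drink_res.relapse_tests.to_csv(outdir / "drinking_relapse_tests.csv", index=False)

        stage = "correlation"
        correlations = _drinking_correlations(feats_imp, drink_res.per_rat)
        if correlations is not None:
            correlations.to_csv(outdir / "drinking_correlations.csv", index=False)
    except Exception as e:
        if isinstance(e, (ValueError, RuntimeError)):
            raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
        raise

    import oddconn

    runlog = {
        "seed": int(seed),
        "version": oddconn.__version__,
        "config": config.to_dict(),
        "excluded_subjects": excluded,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "run_log.json", "w") as f:
        json.dump(runlog, f, indent=2, default=str)
    return {
        "features": feats_imp,
        "anova": anova,
        "paired_t": paired,
        "connectivity": conn_results,
        "connectivity_comparison": conn_comparison,
        "drinking": drink_res,
        "run_log": runlog,
    }


def _drinking_correlations(
    feats: pd.DataFrame, per_rat: pd.DataFrame
) -> pd.DataFrame | None:
    """Partial Spearman correlations of channel-mean post-stimulation
    features in the alcohol group with BL/ADE/relapse, controlling for the
    pre-stimulation value.  Needs at least 5 alcohol subjects."""
    alc = feats[feats["group"] == "alcohol"]
    subjects = sorted(alc["subject"].unique())
    if len(subjects) < 5:
        return None
    chan_mean = (
        alc.groupby(["subject", "treatment", "measure"])["value"].mean().unstack("treatment")
    )
    totals = per_rat[per_rat["concentration"] == "total"].set_index("rat")
    rows = []
    for measure in chan_mean.index.get_level_values("measure").unique():
        sub = chan_mean.xs(measure, level="measure").reindex(subjects)
        for drink_measure in ("BL", "ADE", "relapse"):
            d = totals[drink_measure].reindex(subjects)
            try:
                rho, p = stats_mod.partial_spearman(
                    sub["post"].to_numpy(), d.to_numpy(), sub["pre"].to_numpy()
                )
            except ValueError:
                continue
            rows.append(
                {"measure": measure, "drinking": drink_measure, "rho": rho, "p": p}
            )
    return pd.DataFrame(rows)
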