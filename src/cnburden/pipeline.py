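"""End-to-end orchestration: simulate -> call -> burden -> regions -> survival.

Each stage reads and writes the interchange formats in :mod:`cnburden.io`,
so any prefix of the pipeline can be run and later stages can start from
existing files (e.g. a deposited segment table ingested with
``read_segment_table``).  A JSON run manifest records the config, seed,
stage status and a content digest of every output.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as bd
from . import calling, io, survival as sv
from .genome import GenomeBins
from .regions import REGION_CATALOGUE
from .simulate import OUTCOMES, SimConfig, simulate_cohort

log = logging.getLogger("cnburden")

STAGES = ("simulate", "call", "burden", "regions", "survival", "multiregion")


def _fmt_pct(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.select_dtypes("float"):
        out[col] = out[col].round(2)
    return out


def run_pipeline(config: SimConfig, outdir, stages=STAGES, loss_cut: float = -0.15,
                 gain_cut: float = 0.15, penalty: float | None = None,
                 min_freq: float = 0.20, burden_mode: str = "by_bin",
                 outcomes=("OS", "FFS")) -> dict:
    """Run the requested pipeline stages on a synthetic cohort.

    Returns the manifest dict.  Stage failures are recorded in the manifest
    and prior outputs are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins = GenomeBins.grch37()
    outputs, stage_status = {}, {}
    state: dict = {"bins": bins}

    for stage in stages:
        t0 = time.time()
        try:
            _run_stage(stage, config, outdir, state, outputs,
                       loss_cut=loss_cut, gain_cut=gain_cut, penalty=penalty,
                       min_freq=min_freq, burden_mode=burden_mode, outcomes=outcomes)
            stage_status[stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        except Exception as err:   # noqa: BLE001 — manifest records the failure
            log.error("stage=%s status=failed error=%s", stage, err)
            stage_status[stage] = {"status": "failed", "error": str(err)}
            break
    for stage in STAGES:
        stage_status.setdefault(stage, {"status": "skipped"})
    cfg = json.loads(json.dumps(config.__dict__, default=lambda o: o.__dict__))
    return io.write_manifest(outdir / "manifest.json", cfg, config.seed,
                             outputs, stage_status)


def _need_profiles(state, outdir):
    """Lazy-load called segment profiles from a prior run's segments.tsv."""
    if "profiles" not in state:
        path = Path(outdir) / "segments.tsv"
        if not path.exists():
            raise FileNotFoundError("no called profiles in memory and no segments.tsv "
                                    f"in {outdir}; run the 'call' stage first")
        state["profiles"] = io.read_segment_table(path, state["bins"])
        state["segments"] = io.segments_to_frame(state["profiles"])
    return state["profiles"]


def _need_meta(state, outdir):
    """Lazy-load clinical + truth tables written by a prior simulate stage."""
    if "cohort" not in state:
        clin = Path(outdir) / "clinical.csv"
        truth = Path(outdir) / "truth.tsv"
        if not (clin.exists() and truth.exists()):
            raise FileNotFoundError(f"no cohort tables in {outdir}; run 'simulate' first")
        class _Meta:   # minimal stand-in carrying the two tables
            pass
        m = _Meta()
        m.clinical = io.read_clinical(clin)
        m.truth = pd.read_csv(truth, sep="\t", dtype={"patient_id": str, "sample_id": str})
        state["cohort"] = m
    return state["cohort"]


def _run_stage(stage, config, outdir, state, outputs, *, loss_cut, gain_cut,
               penalty, min_freq, burden_mode, outcomes):
    bins = state["bins"]
    if stage == "simulate":
        cohort = simulate_cohort(config, bins)
        state["cohort"] = cohort
        counts_dir = outdir / "bin_counts"
        counts_dir.mkdir(exist_ok=True)
        for sid, counts in cohort.counts.items():
            p = counts_dir / f"{sid}.tsv"
            io.write_bin_counts(counts, bins, p)
            outputs[f"bin_counts/{sid}"] = p
        io.write_clinical(cohort.clinical, outdir / "clinical.csv")
        cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "run_config.yaml")
        outputs["clinical"] = outdir / "clinical.csv"
        outputs["truth"] = outdir / "truth.tsv"
        outputs["run_config"] = outdir / "run_config.yaml"
        log.info("stage=simulate n_patients=%d n_cores=%d",
                 len(cohort.clinical), len(cohort.truth))

    elif stage == "call":
        cohort = state["cohort"]
        profiles, qc = {}, {}
        for sid, counts in cohort.counts.items():  # noqa: B007
            prof = calling.call_sample(counts, bins, sample_id=sid, penalty=penalty,
                                       loss_cut=loss_cut, gain_cut=gain_cut)
            profiles[sid] = prof
            qc[sid] = prof.qc_mean_segment_sd
        state["profiles"] = profiles
        seg_table = io.segments_to_frame(profiles)
        io.write_segment_table(seg_table, outdir / "segments.tsv")
        with open(outdir / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=2)
        state["segments"] = seg_table
        outputs["segments"] = outdir / "segments.tsv"
        outputs["qc"] = outdir / "qc.json"
        log.info("stage=call n_samples=%d n_segments=%d", len(profiles), len(seg_table))

    elif stage == "burden":
        cohort = _need_meta(state, outdir)
        profiles = _need_profiles(state, outdir)
        records = []
        for sid, prof in profiles.items():
            rec = bd.compute_burden(prof, bins, mode=burden_mode)
            denom = prof.segments.loc[prof.segments["chrom"].isin(
                set(bins.df.loc[bins.autosomal, "chrom"])), "n_bins"].sum()
            loss_bins = prof.segments.loc[prof.segments["call"] == -1, "n_bins"].sum()
            gain_bins = prof.segments.loc[prof.segments["call"] == 1, "n_bins"].sum()
            records.append({"sample_id": sid, "burden": rec.burden,
                            "loss_pct": rec.loss_pct, "gain_pct": rec.gain_pct,
                            "loss_bins": int(loss_bins), "gain_bins": int(gain_bins),
                            "usable_bins": int(denom)})
        bdf = pd.DataFrame(records).merge(
            cohort.truth[["sample_id", "patient_id", "core_id", "is_index"]],
            on="sample_id")
        bdf = bdf.merge(cohort.clinical[["patient_id", "state"]], on="patient_id")
        idx = bdf.loc[bdf["is_index"]].set_index("patient_id")
        labels, bounds = bd.assign_quartiles(idx["burden"])
        idx = idx.assign(quartile=labels)
        bdf = bdf.merge(idx.reset_index()[["patient_id", "quartile"]],
                        on="patient_id", how="left")
        state["burden_table"] = bdf
        state["index_table"] = idx
        _fmt_pct(bdf).to_csv(outdir / "burden.csv", index=False)
        with open(outdir / "quartiles.json", "w") as fh:
            json.dump({"boundaries": bounds,
                       "counts": idx["quartile"].value_counts().to_dict()}, fh, indent=2)
        lg = bd.loss_gain_random_test(idx)
        lg.to_csv(outdir / "loss_gain_test.csv", index=False)
        outputs["burden"] = outdir / "burden.csv"
        outputs["quartiles"] = outdir / "quartiles.json"
        outputs["loss_gain_test"] = outdir / "loss_gain_test.csv"
        log.info("stage=burden n_cores=%d boundaries=%s", len(bdf), bounds)

    elif stage == "regions":
        idx = state["index_table"]
        segments = state["segments"]
        carriers = bd.region_carriers(segments, bins, REGION_CATALOGUE)
        idx_carriers = carriers.loc[carriers.index.isin(idx["sample_id"])]
        idx_carriers.index = idx.reset_index().set_index("sample_id").loc[
            idx_carriers.index, "patient_id"]
        by_state = bd.region_frequency_by_group(idx_carriers,
                                                idx.reset_index().set_index("patient_id")["state"])
        by_quart = bd.region_frequency_by_group(idx_carriers,
                                                idx.reset_index().set_index("patient_id")["quartile"])
        ks = bd.ks_region_association(
            idx.reset_index().set_index("patient_id")["burden"], idx_carriers,
            min_freq=min_freq)
        state["carriers"] = carriers
        _fmt_pct(by_state).to_csv(outdir / "region_freq_by_state.csv")
        _fmt_pct(by_quart).to_csv(outdir / "region_freq_by_quartile.csv")
        ks.to_csv(outdir / "ks_association.csv", index=False)
        outputs["region_freq_by_state"] = outdir / "region_freq_by_state.csv"
        outputs["region_freq_by_quartile"] = outdir / "region_freq_by_quartile.csv"
        outputs["ks_association"] = outdir / "ks_association.csv"
        log.info("stage=regions n_regions_tested=%d", len(ks))

    elif stage == "multiregion":
        bdf = state["burden_table"]
        disp, summary = bd.multiregion_dispersion(bdf)
        _fmt_pct(disp).to_csv(outdir / "dispersion.csv", index=False)
        carriers = state.get("carriers")
        if carriers is not None:
            pmap = bdf.set_index("sample_id")["patient_id"]
            prev = bd.region_prevalence_within_patient(carriers, pmap, REGION_CATALOGUE)
            _fmt_pct(prev).to_csv(outdir / "region_prevalence.csv", index=False)
            outputs["region_prevalence"] = outdir / "region_prevalence.csv"
        with open(outdir / "dispersion_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        outputs["dispersion"] = outdir / "dispersion.csv"
        outputs["dispersion_summary"] = outdir / "dispersion_summary.json"
        log.info("stage=multiregion n_patients=%d", len(disp))

    elif stage == "survival":
        cohort = _need_meta(state, outdir)
        idx = state["index_table"].reset_index()
        data = idx.merge(cohort.clinical, on=["patient_id", "state"])
        enc, adjusters = sv.encode_clinical(data)
        fits, km_rows = {}, []
        for oc in outcomes:
            if oc not in OUTCOMES:
                raise ValueError(f"unknown outcome {oc!r}")
            n_events = int(enc[f"{oc}_event"].sum())
            adj = tuple(adjusters)
            if n_events < 5 * (len(adj) + 1):   # events-per-variable guard
                log.warning("stage=survival outcome=%s n_events=%d too few for %d "
                            "adjusters; fitting unadjusted", oc, n_events, len(adj))
                adj = ()
            fit = sv.select_fp1_cox(enc, oc, adjusters=adj)
            fits[oc] = {"selected_power": fit.selected_power,
                        "best_power": fit.best_power, "coef": fit.coef,
                        "coef_ci": list(fit.coef_ci),
                        "loglik_by_power": fit.loglik_by_power,
                        "loglik_null": fit.loglik_null,
                        "p_inclusion": fit.p_inclusion,
                        "p_linearity": fit.p_linearity,
                        "n": fit.n, "n_events": fit.n_events}
            grid = np.linspace(max(data["burden"].min(), 0.5), data["burden"].max(), 50)
            curve = sv.relative_hazard_curve(fit, grid, reference=grid[0])
            curve.to_csv(outdir / f"hazard_curve_{oc}.csv", index=False)
            outputs[f"hazard_curve_{oc}"] = outdir / f"hazard_curve_{oc}.csv"
            _, km = sv.km_by_quartile(data, oc)
            km.insert(0, "outcome", oc)
            km_rows.append(km)
        with open(outdir / "fp_fits.json", "w") as fh:
            json.dump(fits, fh, indent=2, default=float)
        km_all = pd.concat(km_rows, ignore_index=True)
        _fmt_pct(km_all).to_csv(outdir / "km_4yr.csv", index=False)
        outputs["fp_fits"] = outdir / "fp_fits.json"
        outputs["km_4yr"] = outdir / "km_4yr.csv"
        log.info("stage=survival outcomes=%s", ",".join(outcomes))
    else:
        raise ValueError(f"unknown stage {stage!r}")
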