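"""End-to-end orchestration: synthesize -> CNA -> SOM -> maps -> radiomics
-> clustering -> report.

A single seeded ``RunConfig`` drives every stage; re-running with the same
config reproduces byte-identical outputs. Intermediates are persisted per
stage under the output directory and the final ``RunReport`` summarizes
per-patient index lesions, cohort CNA recurrence by chromosome arm, the
feature filter report and the cluster composition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import arms_overlapped, default_template
from .cna import (CbsConfig, CnaCall, build_core_profiles, cbs_segment,
                  compute_log_ratio, filter_significant, profiles_to_frame,
                  write_cna_bed, write_index_lesion_report, write_seg,
                  CoreProfile)
from .clustering import (adc_group_summary, cluster_composition,
                         filter_features, hsmut_over4, patient_center,
                         plot_cluster_heatmap, ward_correlation_cluster)
from .maps import ToftsFitConfig, ToftsParams, compute_adc, parker_aif
from .radiomics import extract_feature_matrix
from .som import SomConfig, som_sample_correlation
from .synthetic import (ImagePhantomSpec, SyntheticCohortSpec,
                        expected_significant_implants, generate_dce_series,
                        generate_diffusion_pair, generate_probe_tracks,
                        generate_texture_phantoms)

log = logging.getLogger(__name__)

_AGGRESSIVE_TOFTS = ToftsParams(0.25, 0.40, 0.05)
_INDOLENT_TOFTS = ToftsParams(0.08, 0.25, 0.02)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str = "radgen_run"
    seed: int = 0
    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    cbs: CbsConfig = field(default_factory=CbsConfig)
    phantom_shape: tuple[int, int, int] = (64, 64, 14)
    som_epochs: int = 20
    ng: int = 32
    k_clusters: int = 3
    probe_density: float = 3.0
    run_som: bool = True
    run_imaging: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw:
            raw["cohort"] = SyntheticCohortSpec(**raw["cohort"])
        if "cbs" in raw:
            raw["cbs"] = CbsConfig(**raw["cbs"])
        if "phantom_shape" in raw:
            raw["phantom_shape"] = tuple(raw["phantom_shape"])
        return cls(**raw)


@dataclass
class RunReport:
    version: str
    config_seed: int
    n_patients: int
    n_tumor_cores: int
    n_positive_cores: int
    index_lesions: dict[str, list[str]]
    index_lesion_cna_counts: list[int]
    arm_recurrence: list[dict]
    filter_report: dict
    cluster_composition: list[dict]
    adc_by_moltu: list[dict]
    tofts_recovery: dict
    som_within_between: dict | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    def to_markdown(self, path: str | Path) -> None:
        lines = [f"# radgen run report (v{self.version})", "",
                 f"- patients: {self.n_patients}",
                 f"- tumor cores: {self.n_tumor_cores}",
                 f"- cores with >=1 highly significant CNA: {self.n_positive_cores}",
                 f"- genomic index lesions: "
                 f"{sum(len(v) for v in self.index_lesions.values())}", ""]
        lines.append("## Index lesions")
        for pid, cores in sorted(self.index_lesions.items()):
            lines.append(f"- {pid}: {', '.join(cores) or '(none)'}")
        lines.append("")
        lines.append("## Most recurrent arms")
        for row in self.arm_recurrence[:8]:
            lines.append(f"- {row['arm']} {row['direction']}: "
                         f"{row['n_cores']} cores / {row['n_patients']} patients")
        Path(path).write_text("\n".join(lines) + "\n")


def summarize_recurrence(profiles: list[CoreProfile]) -> pd.DataFrame:
    """Per-(arm, direction) counts of distinct cores and patients.

    A call overlapping an arm by >= 1 bp counts on that arm; calls that
    span the centromere count on both arms.
    """
    rows = []
    for p in profiles:
        for c in p.cna_calls:
            for arm in arms_overlapped(c.segment.chrom, c.segment.start,
                                       c.segment.end):
                rows.append((arm, c.direction, p.core_id, p.patient_id))
    if not rows:
        return pd.DataFrame(columns=["arm", "direction", "n_cores", "n_patients"])
    df = pd.DataFrame(rows, columns=["arm", "direction", "core", "patient"])
    out = (df.groupby(["arm", "direction"])
             .agg(n_cores=("core", "nunique"), n_patients=("patient", "nunique"))
             .reset_index()
             .sort_values(["n_cores", "n_patients", "arm"],
                          ascending=[False, False, True], kind="stable")
             .reset_index(drop=True))
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; see module docstring."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    template = default_template(config.probe_density)

    # --- stage 1: synthetic cohort -------------------------------------
    log.info("stage synth: generating cohort")
    cohort = generate_probe_tracks(config.cohort, template)
    cohort.write(out / "cohort")

    # --- stage 2: CNA calling ------------------------------------------
    log.info("stage cna: log ratios, CBS, filtering")
    segments_by_core: dict[str, list] = {}
    calls_by_core: dict[str, list[CnaCall]] = {}
    tracks = {}
    for pid in cohort.patients:
        refs = [cohort.intensities[r] for r in cohort.reference_cores(pid)]
        for cid in cohort.tumor_cores(pid):
            track = compute_log_ratio(cohort.intensities[cid], refs, core_id=cid)
            tracks[cid] = track
            segs = cbs_segment(track, config.cbs)
            segments_by_core[cid] = segs
            calls_by_core[cid] = filter_significant(segs, config.cbs)
    profiles = build_core_profiles(calls_by_core, cohort.manifest)
    write_seg(segments_by_core, out / "segments.seg")
    write_cna_bed(calls_by_core, out / "cna_calls.bed")
    prof_df = profiles_to_frame(profiles)
    prof_df.to_csv(out / "core_profiles.csv", index=False)
    write_index_lesion_report(profiles, out / "index_lesions.json")
    index_lesions = {
        pid: sorted(p.core_id for p in profiles
                    if p.patient_id == pid and p.hi_les)
        for pid in cohort.patients}
    lesion_counts = sorted((p.hs_mut for p in profiles if p.hi_les), reverse=True)
    recurrence = summarize_recurrence(profiles)
    recurrence.to_csv(out / "arm_recurrence.csv", index=False)

    # --- stage 3: SOM metagene correlation ------------------------------
    som_summary = None
    if config.run_som:
        log.info("stage som: 400-metagene sample correlation")
        tumor_ids = list(tracks)
        probe_matrix = pd.DataFrame(
            {cid: tracks[cid].table["log2_ratio"].to_numpy() for cid in tumor_ids})
        corr = som_sample_correlation(
            probe_matrix, SomConfig(epochs=config.som_epochs, seed=config.seed))
        corr.to_csv(out / "som_sample_correlation.csv")
        pat_of = {cid: cid.split("_")[0] for cid in tumor_ids}
        within, between = [], []
        for i, a in enumerate(tumor_ids):
            for b in tumor_ids[i + 1:]:
                (within if pat_of[a] == pat_of[b] else between).append(
                    corr.loc[a, b])
        som_summary = {"mean_within_patient_r": float(np.mean(within)),
                       "mean_between_patient_r": float(np.mean(between))}

    # --- stage 4 + 5: imaging phantoms, maps, radiomics -----------------
    features = None
    adc_summary_rows: list[dict] = []
    tofts_recovery: dict = {}
    comp_rows: list[dict] = []
    filt_dict: dict = {}
    if config.run_imaging:
        log.info("stage maps: phantoms, ADC, per-VOI Tofts fits")
        prof_by_core = {p.core_id: p for p in profiles}
        tumor_manifest = cohort.manifest[cohort.manifest.role == "tumor"]
        voi_of_core = dict(zip(tumor_manifest.core_id, tumor_manifest.voi_id))
        # ground-truth aggressiveness drives the phantom texture class
        labels = {}
        pat_of_voi = {}
        for cid, voi in voi_of_core.items():
            n_sig = len(expected_significant_implants(
                cohort.ledger[cid], template,
                config.cbs.threshold, config.cbs.min_length_bp))
            labels[voi] = "aggressive" if n_sig >= 1 else "indolent"
            pat_of_voi[voi] = prof_by_core[cid].patient_id
        spec = ImagePhantomSpec(shape=config.phantom_shape,
                                seed=config.seed + 101)
        maps, masks, _ = generate_texture_phantoms(
            spec, labels, patient_of_voi=pat_of_voi, patient_offset_sd=0.8)

        # ADC map recomputed from a synthetic b0/b1500 pair (exact inverse)
        adc_vol = maps["ADC1500"]
        s0 = np.full(adc_vol.data.shape, 1000.0)
        b0, b1500 = generate_diffusion_pair(
            adc_vol.data * 1e-6, s0, noise_sd=0.0, spacing=spec.spacing)
        maps["ADC1500"] = compute_adc(b0, b1500)
        maps["B1500"] = b1500
        for kind, vol in maps.items():
            vol.to_nifti(out / f"map_{kind}.nii.gz")

        # per-VOI Tofts fit on the mean DCE curve (class-dependent truth)
        times = np.arange(0.0, 5.0 + 1e-9, 5.0 / 60.0)
        aif = parker_aif(times)
        errs = {"Ktrans": [], "ve": []}
        rng = np.random.default_rng([config.seed, 7])
        from .maps import fit_tofts
        for voi, lab in labels.items():
            truth = _AGGRESSIVE_TOFTS if lab == "aggressive" else _INDOLENT_TOFTS
            curve = generate_dce_series(truth, aif, times, noise_sd=0.002,
                                        seed=int(rng.integers(2 ** 31)))
            fit = fit_tofts(curve, aif, times,
                            ToftsFitConfig(seed=config.seed + 13))
            errs["Ktrans"].append(abs(fit.params.ktrans - truth.ktrans)
                                  / truth.ktrans)
            errs["ve"].append(abs(fit.params.ve - truth.ve) / truth.ve)
        tofts_recovery = {f"median_rel_err_{k}": float(np.median(v))
                          for k, v in errs.items()}

        log.info("stage radiomics: %d VOIs x 2352 features", len(masks))
        features = extract_feature_matrix(
            [(maps, m) for m in masks], ng=config.ng)
        features.to_csv(out / "feature_matrix.csv")

        # --- stage 6: clustering ----------------------------------------
        log.info("stage cluster: filter, patient-center, Ward.D")
        ann = prof_df.set_index("core_id").copy()
        ann.index = [voi_of_core[c] for c in ann.index]
        ann.index.name = "voi_id"
        filtered, filt_report = filter_features(features)
        centered = patient_center(filtered, [pat_of_voi[v] for v in filtered.index])
        result = ward_correlation_cluster(centered, k=config.k_clusters)
        comp = cluster_composition(
            result, ann.assign(patient_id=[pat_of_voi[v] for v in ann.index]))
        comp.to_csv(out / "cluster_composition.csv")
        result.labels.to_csv(out / "cluster_labels.csv")
        filt_dict = {"n_input_features": filt_report.n_input_features,
                     "n_removed": filt_report.n_removed,
                     "n_retained": filt_report.n_retained}
        comp_rows = comp.reset_index().to_dict("records")
        if config.make_plots:
            plot_cluster_heatmap(
                centered, result,
                ann.assign(patient_id=[pat_of_voi[v] for v in ann.index]),
                str(out / "cluster_heatmap.png"))

        # ADC vs aggressiveness: mean in-VOI ADC grouped by MolTu
        adc_map = maps["ADC1500"].data
        adc_means = pd.Series(
            {m.voi_id: float(adc_map[m.mask].mean()) for m in masks})
        moltu = ann["MolTu"].map({True: "MolTu+", False: "MolTu-"})
        adc_tab = adc_group_summary(adc_means, moltu.loc[adc_means.index])
        adc_tab.to_csv(out / "adc_by_moltu.csv")
        adc_summary_rows = adc_tab.reset_index().to_dict("records")

    report = RunReport(
        version=__version__,
        config_seed=config.seed,
        n_patients=len(cohort.patients),
        n_tumor_cores=len(tracks),
        n_positive_cores=int((prof_df["hsMut"] >= 1).sum()),
        index_lesions=index_lesions,
        index_lesion_cna_counts=lesion_counts,
        arm_recurrence=recurrence.to_dict("records"),
        filter_report=filt_dict,
        cluster_composition=comp_rows,
        adc_by_moltu=adc_summary_rows,
        tofts_recovery=tofts_recovery,
        som_within_between=som_summary,
    )
    report.to_json(out / "report.json")
    report.to_markdown(out / "report.md")
    return report
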