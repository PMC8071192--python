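"""End-to-end experiment pipeline and artifact I/O.

Orchestrates generate -> acquire -> reconstruct -> quantify -> analyze for a
whole synthetic cohort, producing a report that mirrors a full study readout:
group summaries, Mann-Whitney comparisons, partial correlations with tumor
type as covariate, stepwise regression models for elasticity, viscosity and
the compression stiffening rate, ROC analyses of the two candidate markers,
test-retest repeatability, and provenance (config hash + seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from . import compression_analysis as ca
from . import histo_quant as hq
from . import mre_recon as mr
from . import synthetic_data as sd

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "load_config",
    "default_config_path",
    "run_experiment",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_acquisition_nifti",
    "read_acquisition_nifti",
    "write_elastogram_nifti",
    "write_report_json",
    "read_report_json",
]

MECH_VARS = ("elasticity", "viscosity", "stiffening_slope")
COVARIATE_VARS = ("solid_stress", "interstitial_fluid_pressure", "volume",
                  "collagen_fraction", "cellularity")
SUMMARY_VARS = MECH_VARS + COVARIATE_VARS

_COHORT_COLUMNS = [
    "subject_id", "tumor_type",
    "true_solid_stress", "true_interstitial_fluid_pressure", "true_volume",
    "true_collagen_fraction", "true_cellularity", "true_basal_elasticity",
    "true_basal_viscosity", "true_stiffening_slope",
    "elasticity", "viscosity", "stiffening_slope",
    "solid_stress", "interstitial_fluid_pressure", "volume",
    "collagen_fraction", "cellularity",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Validated experiment configuration (see ``data/paper_cohort.yaml``)."""

    seed: int = 0
    cohort: sd.CohortConfig = field(default_factory=sd.CohortConfig)
    simulate_waves: bool = True
    simulate_histology: bool = True
    geometry: sd.AcquisitionGeometry = field(
        default_factory=sd.AcquisitionGeometry)
    roi_fraction: float = 0.75
    solid_stress_cutoff_mmhg: float = 15.6
    collagen_cutoff_percent: float = 1.7
    stepwise_p_enter: float = 0.05
    stepwise_p_remove: float = 0.10
    n_repeatability_subjects: int = 5
    picrosirius_tile: tuple[int, int] = (384, 384)
    picrosirius_pixel_um: float = 2.0
    nucleus_field_area_mm2: float = 1.0
    nucleus_overlap_fraction: float = 0.1
    nucleus_pixel_um: float = 1.0
    save_nifti: bool = True
    save_tiles: bool = True

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["covariate_correlations"] = np.asarray(
            self.cohort.covariate_correlations).tolist()
        d["geometry"]["encoding_directions"] = np.asarray(
            self.geometry.encoding_directions).tolist()
        return d

    def hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_CONFIG_SECTIONS = {
    "seed", "cohort", "acquisition", "histology", "analysis", "outputs"}


def default_config_path() -> Path:
    return Path(resources.files("elastocomp") / "data" / "paper_cohort.yaml")


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys raise with
    their full key path."""
    path = Path(path) if path is not None else default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = ExperimentConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])

    cohort_raw = dict(raw.get("cohort") or {})
    cohort_fields = {f.name for f in dataclasses.fields(sd.CohortConfig)}
    for key, value in cohort_raw.items():
        if key not in cohort_fields:
            raise ValueError(f"unknown config key: cohort.{key}")
        if key == "covariate_correlations":
            value = np.asarray(value, dtype=float)
        if key == "compression_levels_kpa":
            value = tuple(float(v) for v in value)
        setattr(cfg.cohort, key, value)
    cfg.cohort.validate()

    acq = dict(raw.get("acquisition") or {})
    cfg.simulate_waves = bool(acq.pop("simulate_waves", cfg.simulate_waves))
    cfg.roi_fraction = float(acq.pop("roi_fraction", cfg.roi_fraction))
    geom_fields = {f.name for f in dataclasses.fields(sd.AcquisitionGeometry)}
    geom_kwargs = {}
    for key, value in acq.items():
        if key not in geom_fields:
            raise ValueError(f"unknown config key: acquisition.{key}")
        if key == "voxel_size_um":
            value = tuple(float(v) for v in value)
        geom_kwargs[key] = value
    if geom_kwargs:
        cfg.geometry = sd.AcquisitionGeometry(**geom_kwargs)

    histo = dict(raw.get("histology") or {})
    mapping = {"simulate": ("simulate_histology", bool),
               "picrosirius_tile": ("picrosirius_tile", lambda v: tuple(int(x) for x in v)),
               "picrosirius_pixel_um": ("picrosirius_pixel_um", float),
               "nucleus_field_area_mm2": ("nucleus_field_area_mm2", float),
               "nucleus_overlap_fraction": ("nucleus_overlap_fraction", float),
               "nucleus_pixel_um": ("nucleus_pixel_um", float)}
    for key, value in histo.items():
        if key not in mapping:
            raise ValueError(f"unknown config key: histology.{key}")
        attr, conv = mapping[key]
        setattr(cfg, attr, conv(value))

    ana = dict(raw.get("analysis") or {})
    mapping = {"solid_stress_cutoff_mmhg": float,
               "collagen_cutoff_percent": float,
               "stepwise_p_enter": float, "stepwise_p_remove": float,
               "n_repeatability_subjects": int}
    for key, value in ana.items():
        if key not in mapping:
            raise ValueError(f"unknown config key: analysis.{key}")
        setattr(cfg, key, mapping[key](value))

    outs = dict(raw.get("outputs") or {})
    for key, value in outs.items():
        if key not in ("save_nifti", "save_tiles"):
            raise ValueError(f"unknown config key: outputs.{key}")
        setattr(cfg, key, bool(value))
    return cfg


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    group_summaries: dict
    comparison_p: dict
    partial_correlations: dict
    stepwise_models: dict
    roc_results: dict
    repeatability: dict | None
    n_analyzed: dict
    exclusions: list
    warnings: list
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentReport":
        names = {f.name for f in dataclasses.fields(cls)}
        missing = names - set(d)
        if missing:
            raise ValueError(f"report is missing field(s): {sorted(missing)}")
        return cls(**{k: d[k] for k in names})


# --------------------------------------------------------------------------
# per-subject measurement
# --------------------------------------------------------------------------

def measure_subject_mechanics(subject: sd.SubjectTruth,
                              config: ExperimentConfig,
                              seed_seq: np.random.SeedSequence,
                              outdir: Path | None = None):
    """Simulate + reconstruct one subject at every compression level.

    Returns (basal G', basal G'', stiffening fit, per-level list) or raises
    ``RuntimeError`` naming the failed stage when fewer than two levels give
    a usable reconstruction (mirroring in vivo exclusions).
    """
    geom = config.geometry
    roi = mr.central_roi(geom, config.roi_fraction)
    seeds = seed_seq.spawn(len(config.cohort.compression_levels_kpa))
    levels = []
    for comp, s in zip(config.cohort.compression_levels_kpa, seeds):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                acq = sd.simulate_wave_acquisition(
                    subject, comp, geom, seed=s.generate_state(1)[0],
                    noise_sd=config.cohort.phase_noise_sd_rad)
                maps = mr.reconstruct(acq)
            st = mr.roi_statistics(maps, roi)
        except ValueError:
            continue
        levels.append((comp, st.mean_storage_kpa, st.mean_loss_kpa))
        if outdir is not None and comp == 0.0:
            write_elastogram_nifti(
                maps, geom, outdir / f"{subject.subject_id}_basal")
    if len(levels) < 2:
        raise RuntimeError("reconstruction failed at all but "
                           f"{len(levels)} compression level(s)")
    if levels[0][0] != 0.0:
        raise RuntimeError("basal reconstruction failed")
    fit = ca.stiffening_rate(ca.CompressionSeries(
        points=[(c, gp) for c, gp, _ in levels],
        subject_id=subject.subject_id))
    return levels[0][1], levels[0][2], fit, levels


def _measure_histology(subject: sd.SubjectTruth, config: ExperimentConfig,
                       seed_seq: np.random.SeedSequence,
                       outdir: Path | None = None):
    s1, s2 = seed_seq.spawn(2)
    picro = sd.render_picrosirius_slide(
        subject.collagen_fraction, config.picrosirius_tile,
        config.picrosirius_pixel_um, seed=s1.generate_state(1)[0])
    nuc = sd.render_nucleus_field(
        subject.cellularity, config.nucleus_field_area_mm2,
        config.nucleus_overlap_fraction, config.nucleus_pixel_um,
        seed=s2.generate_state(1)[0])
    coll = hq.collagen_fraction(picro).collagen_fraction
    dens = hq.count_nuclei(nuc).cell_density
    if outdir is not None:
        import tifffile
        tifffile.imwrite(outdir / f"{subject.subject_id}_picrosirius.tif",
                         picro.pixels,
                         resolution=(1e4 / config.picrosirius_pixel_um,) * 2)
        tifffile.imwrite(outdir / f"{subject.subject_id}_nucleus.tif",
                         nuc.pixels,
                         resolution=(1e4 / config.nucleus_pixel_um,) * 2)
    return coll, dens


# --------------------------------------------------------------------------
# the full experiment
# --------------------------------------------------------------------------

def build_measured_table(config: ExperimentConfig,
                         seed: int | None = None,
                         outdir: Path | None = None):
    """Generate the cohort and measure every subject.

    Returns (DataFrame, exclusions, warnings_list).  With
    ``simulate_waves=False`` the mechanical measurements equal the ground
    truth (fast mode for statistics-only workflows); pressures and histology
    are always measured through their simulators.
    """
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    cohort_seed, wave_seed, press_seed, histo_seed = root.spawn(4)
    subjects = sd.sample_cohort(config.cohort,
                                seed=cohort_seed.generate_state(1)[0])
    wave_seqs = wave_seed.spawn(len(subjects))
    press_seqs = press_seed.spawn(len(subjects))
    histo_seqs = histo_seed.spawn(len(subjects))

    rows, exclusions, warns = [], [], []
    for subject, ws, ps, hs in zip(subjects, wave_seqs, press_seqs, histo_seqs):
        row = {
            "subject_id": subject.subject_id,
            "tumor_type": subject.tumor_type,
            "true_solid_stress": subject.solid_stress,
            "true_interstitial_fluid_pressure":
                subject.interstitial_fluid_pressure,
            "true_volume": subject.volume,
            "true_collagen_fraction": subject.collagen_fraction,
            "true_cellularity": subject.cellularity,
            "true_basal_elasticity": subject.basal_elasticity,
            "true_basal_viscosity": subject.basal_viscosity,
            "true_stiffening_slope": subject.stiffening_slope,
        }
        if config.simulate_waves:
            try:
                gp, gpp, fit, _ = measure_subject_mechanics(
                    subject, config, ws, outdir)
            except RuntimeError as exc:
                exclusions.append({"subject_id": subject.subject_id,
                                   "reason": str(exc)})
                continue
            row.update(elasticity=gp, viscosity=gpp,
                       stiffening_slope=fit.slope)
        else:
            row.update(elasticity=subject.basal_elasticity,
                       viscosity=subject.basal_viscosity,
                       stiffening_slope=subject.stiffening_slope)
        press = sd.simulate_pressure_readings(
            subject, config.cohort.pressure_noise_sd_mmhg,
            seed=ps.generate_state(1)[0])
        row.update(solid_stress=press.solid_stress,
                   interstitial_fluid_pressure=press.interstitial_fluid_pressure,
                   volume=subject.volume)
        if config.simulate_histology:
            coll, dens = _measure_histology(subject, config, hs, outdir)
            row.update(collagen_fraction=coll, cellularity=dens)
        else:
            row.update(collagen_fraction=subject.collagen_fraction,
                       cellularity=subject.cellularity)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    return df, exclusions, warns


def _repeatability(config: ExperimentConfig,
                   seed: int) -> dict | None:
    """Scan the first HCC subjects twice (independent noise) and compute the
    repeatability indexes of elasticity, viscosity and stiffening rate."""
    if not config.simulate_waves or config.n_repeatability_subjects < 2:
        return None
    root = np.random.SeedSequence(seed)
    cohort_seed, _, _, _, retest_seed = root.spawn(5)
    subjects = [s for s in sd.sample_cohort(
        config.cohort, seed=cohort_seed.generate_state(1)[0])
        if s.tumor_type == "HCC"][:config.n_repeatability_subjects]
    seqs = retest_seed.spawn(2 * len(subjects))
    pairs = {"elasticity": [], "viscosity": [], "stiffening_slope": []}
    for i, subject in enumerate(subjects):
        try:
            m1 = measure_subject_mechanics(subject, config, seqs[2 * i])
            m2 = measure_subject_mechanics(subject, config, seqs[2 * i + 1])
        except RuntimeError:
            continue
        pairs["elasticity"].append((m1[0], m2[0]))
        pairs["viscosity"].append((m1[1], m2[1]))
        slopes = (m1[2].slope, m2[2].slope)
        if min(slopes) > 0:   # relative differences need positive values
            pairs["stiffening_slope"].append(slopes)
    out = {}
    for name, p in pairs.items():
        out[name] = ca.repeatability_index(p) if len(p) >= 2 else None
    out["n_pairs"] = {k: len(v) for k, v in pairs.items()}
    return out


def analyze_cohort(df: pd.DataFrame, config: ExperimentConfig):
    """The statistical battery on a measured cohort table."""
    warns = []
    hcc = df[df.tumor_type == "HCC"]
    cca = df[df.tumor_type == "CCA"]
    summaries, comparisons = {}, {}
    for var in SUMMARY_VARS:
        summaries[var] = {
            g: {"mean": float(sub[var].mean()),
                "sd": float(sub[var].std(ddof=1))}
            for g, sub in (("HCC", hcc), ("CCA", cca))}
        try:
            _, p = cs.mann_whitney(hcc[var].values, cca[var].values)
            comparisons[var] = p
        except ValueError as exc:
            comparisons[var] = None
            warns.append(f"Mann-Whitney failed for {var}: {exc}")

    tumor_type = (df.tumor_type == "CCA").astype(float).values
    partials = {}
    for mech in MECH_VARS:
        partials[mech] = {}
        for cov in COVARIATE_VARS:
            try:
                r, p = cs.partial_correlation(
                    df[cov].values, df[mech].values, tumor_type)
                partials[mech][cov] = {"r": r, "p": p}
            except ValueError as exc:
                partials[mech][cov] = None
                warns.append(f"partial correlation {mech}~{cov} failed: {exc}")

    candidates = {cov: df[cov].values for cov in COVARIATE_VARS}
    candidates["tumor_type"] = tumor_type
    stepwise = {}
    for mech in MECH_VARS:
        try:
            model = cs.stepwise_regression(
                df[mech].values, candidates,
                p_enter=config.stepwise_p_enter,
                p_remove=config.stepwise_p_remove, response_name=mech)
            stepwise[mech] = dataclasses.asdict(model)
        except ValueError as exc:
            stepwise[mech] = None
            warns.append(f"stepwise regression for {mech} failed "
                         f"(degenerate n): {exc}")

    roc = {}
    roc_specs = {
        "stiffening_rate_vs_solid_stress": (
            "stiffening_slope", "solid_stress",
            config.solid_stress_cutoff_mmhg, True),
        "elasticity_vs_solid_stress": (
            "elasticity", "solid_stress",
            config.solid_stress_cutoff_mmhg, False),
        "elasticity_vs_collagen": (
            "elasticity", "collagen_fraction",
            config.collagen_cutoff_percent, False),
        "stiffening_rate_vs_collagen": (
            "stiffening_slope", "collagen_fraction",
            config.collagen_cutoff_percent, True),
    }
    for name, (score, target, cutoff, negate) in roc_specs.items():
        labels = cs.dichotomize(df[target].values, cutoff)
        try:
            res = cs.roc_auc(df[score].values, labels, negate=negate,
                             threshold_definition={
                                 "variable": target, "cutoff": cutoff,
                                 "direction": "ge"})
            roc[name] = dataclasses.asdict(res)
        except ValueError as exc:
            roc[name] = None
            warns.append(f"ROC {name} failed: {exc}")
    return summaries, comparisons, partials, stepwise, roc, warns


def run_experiment(config: ExperimentConfig | str | Path | None = None,
                   outdir: str | Path | None = None,
                   seed: int | None = None) -> ExperimentReport:
    """Run the whole experiment and (optionally) persist all artifacts."""
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    seed = config.seed if seed is None else seed
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
    artifact_dir = out if (out is not None and
                           (config.save_nifti or config.save_tiles)) else None

    df, exclusions, warns = build_measured_table(config, seed, artifact_dir)
    if len(df) < 4:
        warns.append("fewer than 4 analyzed subjects; statistics degenerate")
    summaries, comparisons, partials, stepwise, roc, stat_warns = \
        analyze_cohort(df, config)
    warns.extend(stat_warns)
    if min(config.cohort.n_hcc, config.cohort.n_cca) < 5:
        warns.append("statistics computed at degenerate group size")
    repeat = _repeatability(config, seed)

    report = ExperimentReport(
        group_summaries=summaries,
        comparison_p=comparisons,
        partial_correlations=partials,
        stepwise_models=stepwise,
        roc_results=roc,
        repeatability=repeat,
        n_analyzed={"HCC": int((df.tumor_type == "HCC").sum()),
                    "CCA": int((df.tumor_type == "CCA").sum())},
        exclusions=exclusions,
        warnings=warns,
        provenance={"config_hash": config.hash(), "seed": int(seed)},
    )
    if out is not None:
        write_cohort_csv(df, out / "cohort.csv")
        write_report_json(report, out / "report.json")
        (out / "report.txt").write_text(format_report(report))
    return report


def format_report(report: ExperimentReport) -> str:
    """Human-readable summary table (values rounded to display precision)."""
    lines = ["Synthetic compression-MRE experiment report",
             f"analyzed: {report.n_analyzed['HCC']} HCC + "
             f"{report.n_analyzed['CCA']} CCA "
             f"({len(report.exclusions)} excluded)", ""]
    lines.append(f"{'variable':32s}{'HCC mean±SD':>18s}{'CCA mean±SD':>18s}"
                 f"{'p (MW)':>10s}")
    for var, s in report.group_summaries.items():
        p = report.comparison_p.get(var)
        lines.append(
            f"{var:32s}"
            f"{s['HCC']['mean']:10.2f}±{s['HCC']['sd']:<6.2f}"
            f"{s['CCA']['mean']:10.2f}±{s['CCA']['sd']:<6.2f}"
            + (f"{p:>10.3f}" if p is not None else f"{'n/a':>10s}"))
    lines.append("")
    for name, r in report.roc_results.items():
        if r is not None:
            lines.append(f"AUC {name}: {r['auc']:.2f} ± {r['se']:.2f} "
                         f"(p={r['p_vs_half']:.4f})")
    if report.repeatability:
        rep = {k: v for k, v in report.repeatability.items()
               if k != "n_pairs" and v is not None}
        lines.append("")
        lines.append("repeatability indexes (%): " + ", ".join(
            f"{k} {v:.0f}" for k, v in rep.items()))
    lines.append("")
    lines.append(f"provenance: config {report.provenance['config_hash']} "
                 f"seed {report.provenance['seed']}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# artifact I/O
# --------------------------------------------------------------------------

def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {missing}")
    return df


def _affine_um(geometry: sd.AcquisitionGeometry) -> np.ndarray:
    r, c, s = geometry.voxel_size_um
    return np.diag([c, r, s, 1.0])


def write_acquisition_nifti(acq: sd.WaveAcquisition,
                            directory: str | Path,
                            prefix: str = "phase") -> None:
    """One NIfTI per (direction, offset), zooms in micrometres, plus a JSON
    sidecar with the acquisition geometry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geom = acq.geometry
    affine = _affine_um(geom)
    for d in range(3):
        for m in range(geom.n_offsets):
            vol = np.transpose(acq.wrapped_phase[d, m], (2, 1, 0))
            img = nib.Nifti1Image(vol.astype(np.float64), affine)
            img.header.set_xyzt_units(xyz="micron")
            nib.save(img, directory / f"{prefix}_dir{d}_off{m}.nii.gz")
    sidecar = {
        "matrix_rows": geom.matrix_rows, "matrix_cols": geom.matrix_cols,
        "n_slices": geom.n_slices,
        "voxel_size_um": list(geom.voxel_size_um),
        "vibration_frequency_hz": geom.vibration_frequency_hz,
        "n_offsets": geom.n_offsets,
        "encoding_directions": np.asarray(geom.encoding_directions).tolist(),
        "encoding_efficiency_rad_per_um": geom.encoding_efficiency_rad_per_um,
        "noise_sd": acq.noise_sd,
    }
    (directory / f"{prefix}_geometry.json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def read_acquisition_nifti(directory: str | Path,
                           prefix: str = "phase") -> sd.WaveAcquisition:
    directory = Path(directory)
    sidecar_path = directory / f"{prefix}_geometry.json"
    if not sidecar_path.exists():
        raise ValueError(f"missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    noise_sd = meta.pop("noise_sd", 0.0)
    meta["voxel_size_um"] = tuple(meta["voxel_size_um"])
    meta["encoding_directions"] = np.asarray(meta["encoding_directions"])
    geom = sd.AcquisitionGeometry(**meta)
    phases = np.empty((3, geom.n_offsets) + geom.shape)
    for d in range(3):
        for m in range(geom.n_offsets):
            p = directory / f"{prefix}_dir{d}_off{m}.nii.gz"
            if not p.exists():
                raise ValueError(f"missing volume {p.name}")
            img = nib.load(p)
            phases[d, m] = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    return sd.WaveAcquisition(geometry=geom, wrapped_phase=phases,
                              noise_sd=noise_sd)


def write_elastogram_nifti(maps: mr.ElastogramMaps,
                           geometry: sd.AcquisitionGeometry,
                           prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = _affine_um(geometry)
    for suffix, vol in (("storage", maps.storage_modulus),
                        ("loss", maps.loss_modulus),
                        ("valid", maps.validity_mask.astype(np.uint8))):
        img = nib.Nifti1Image(
            np.transpose(vol, (2, 1, 0)).astype(np.float32), affine)
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, f"{prefix}_{suffix}.nii.gz")


def write_report_json(report: ExperimentReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json())


def read_report_json(path: str | Path) -> ExperimentReport:
    return ExperimentReport.from_dict(json.loads(Path(path).read_text()))
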