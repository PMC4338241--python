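"""End-to-end in-silico study: seeded patient cohort, five superimposition
techniques x simulated operators x repeated sessions, a duplicate-model
control arm, measurement tables and the statistical analyses, with TSV /
figure / mesh report export.

Everything derives deterministically from ``StudyConfig.master_seed``: child
seeds for phantom construction, the rescan transform, operator picks and ICP
sampling are drawn from per-cell seed tuples, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .geometry import RigidTransform
from .metrics import accuracy_D, deviation_field, landmark_displacement
from .phantom import (
    FIDUCIAL_PATCH_CENTERS,
    MEASUREMENT_POINTS,
    PhantomSpec,
    apply_treatment,
    build_phantom,
    compose_rescan,
    jitter_operator,
    simulate_rescan,
)
from .register import Bundle, IcpParams, TECHNIQUES, superimpose
from .stats import bland_altman, pairwise_posthoc, permanova, permdisp
from .surface import (
    circular_patch,
    clean_components,
    decimate_to_budget,
    extract_isosurface,
    write_stl,
)

__all__ = ["StudyConfig", "run_study", "run_duplicate_control", "run_statistics", "make_report"]

log = logging.getLogger("cranioreg")

ACCURACY_PATCH_AREA_MM2 = 5.0
GOLD_STANDARD = "ACF"


@dataclass
class StudyConfig:
    """Study design: sizes, phantom conditions, registration settings."""

    n_patients: int = 8
    techniques: tuple = TECHNIQUES
    n_operators: int = 3
    n_sessions: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    icp: IcpParams = field(default_factory=lambda: IcpParams(sample_count=3000))
    operator_jitter_sd_mm: float = 0.75
    region_jitter_fraction: float = 0.2
    threshold_hu: float = 500.0
    max_faces: int = 100_000
    clean_min_fraction: float = 0.002
    master_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ValueError(f"unknown techniques: {sorted(unknown)}")


def _seed(*parts) -> int:
    """Deterministic child seed < 2**31 from a tuple of small integers."""
    h = np.random.SeedSequence([int(p) % (2**31) for p in parts])
    return int(h.generate_state(1)[0] % (2**31))


def _prepare_mesh(volume, config: StudyConfig):
    mesh = extract_isosurface(volume, config.threshold_hu)
    mesh = clean_components(mesh, config.clean_min_fraction)
    return decimate_to_budget(mesh, config.max_faces)


def _build_patient(config: StudyConfig, patient: int, treated: bool = True):
    """Phantom T0/T1 pair for one patient (T1 = treated + rescanned)."""
    spec = replace(config.phantom, seed=_seed(config.master_seed, patient, 1))
    vol0, truth, atlas = build_phantom(spec)
    mesh0 = _prepare_mesh(vol0, config)
    if treated:
        vol_t, truth, atlas_t = apply_treatment(vol0, truth, atlas, spec)
    else:
        vol_t, atlas_t = vol0, atlas
    rng = np.random.default_rng(_seed(config.master_seed, patient, 2))
    vol1, rescan = simulate_rescan(vol_t, spec, rng)
    truth, atlas1 = compose_rescan(truth, atlas_t, rescan)
    mesh1 = _prepare_mesh(vol1, config)
    log.info(
        "patient %d: meshes %d/%d faces, rescan rotation %.2f deg",
        patient, mesh0.n_faces, mesh1.n_faces, rescan.rotation_angle_deg(),
    )
    return dict(
        spec=spec, truth=truth, atlas0=atlas, atlas1=atlas1,
        mesh0=mesh0, mesh1=mesh1, rescan=rescan,
    )


def _measure_cell(tech, tf, report, pat, bundle_meta, lm0, lm1, cell_seed):
    """Accuracy and precision records for one registration."""
    mesh0, mesh1 = bundle_meta["mesh0"], bundle_meta["mesh1"]
    reg1 = mesh1.transformed(tf)
    patches = []
    for name in FIDUCIAL_PATCH_CENTERS:
        center = tf.apply(lm1[name])
        patches.append(
            circular_patch(
                reg1, center, ACCURACY_PATCH_AREA_MM2, label=name,
                max_center_dist_mm=10.0,
            )
        )
    acc = accuracy_D(reg1, mesh0, patches, seed=cell_seed)
    acc_row = dict(
        D=acc.D_accuracy,
        Dx=float(np.mean([r.Dx for r in acc.patch_deviations])),
        Dy=float(np.mean([r.Dy for r in acc.patch_deviations])),
        Dz=float(np.mean([r.Dz for r in acc.patch_deviations])),
        converged=bool(report.converged) if report is not None else True,
        iterations=report.iterations_run if report is not None else 0,
    )
    prec_rows = []
    for pt in MEASUREMENT_POINTS:
        rec = landmark_displacement(lm0[pt], lm1[pt], tf, label=pt)
        prec_rows.append(dict(unit=pt, D=rec.D, Dx=rec.Dx, Dy=rec.Dy, Dz=rec.Dz))
    return acc_row, prec_rows


def run_study(config: StudyConfig):
    """The full protocol: for every patient build the phantom pair, then for
    each technique x operator x session register T1 onto T0 and record the
    accuracy (fiducial patches) and precision (landmark displacement) rows.

    Returns ``(accuracy_table, precision_table, reports)``. Cell-level
    failures are recorded in ``reports['errors']`` and the run continues.
    """
    acc_rows, prec_rows = [], []
    reports = {"errors": [], "patients": {}}
    for pat in range(config.n_patients):
        meta = _build_patient(config, pat, treated=True)
        truth = meta["truth"]
        reports["patients"][pat] = {
            "rescan_rotation_deg": meta["rescan"].rotation_angle_deg(),
            "faces_t0": meta["mesh0"].n_faces,
            "faces_t1": meta["mesh1"].n_faces,
        }
        for op in range(config.n_operators):
            for sess in range(config.n_sessions):
                lm0, atlas0 = jitter_operator(
                    truth.landmarks_t0, meta["atlas0"],
                    config.operator_jitter_sd_mm,
                    np.random.default_rng(_seed(config.master_seed, pat, op, sess, 10)),
                    mesh=meta["mesh0"],
                    region_fraction=config.region_jitter_fraction,
                )
                lm1, atlas1 = jitter_operator(
                    truth.landmarks_t1, meta["atlas1"],
                    config.operator_jitter_sd_mm,
                    np.random.default_rng(_seed(config.master_seed, pat, op, sess, 11)),
                    mesh=meta["mesh1"],
                    region_fraction=config.region_jitter_fraction,
                )
                b0 = Bundle(meta["mesh0"], lm0, atlas0)
                b1 = Bundle(meta["mesh1"], lm1, atlas1)
                for tech in config.techniques:
                    key = dict(patient=pat, technique=tech, operator=op + 1, session=sess + 1)
                    cell_seed = _seed(config.master_seed, pat, op, list(TECHNIQUES).index(tech))
                    try:
                        tf, rep = superimpose(
                            tech, b0, b1, replace(config.icp, seed=cell_seed)
                        )
                        acc_row, p_rows = _measure_cell(
                            tech, tf, rep, pat, meta, lm0, lm1, cell_seed
                        )
                    except Exception as exc:  # record and continue
                        log.warning("cell %s failed: %s", key, exc)
                        reports["errors"].append({**key, "error": str(exc)})
                        continue
                    acc_rows.append({**key, "unit": "fiducials", **acc_row})
                    for pr in p_rows:
                        prec_rows.append({**key, **pr})
    accuracy = pd.DataFrame(acc_rows)
    precision = pd.DataFrame(prec_rows)
    return accuracy, precision, reports


def run_duplicate_control(config: StudyConfig):
    """Control arm: superimpose a rigidly displaced duplicate of each
    patient's pre-treatment mesh (no treatment, no new scan noise). One
    operator; landmark picks are jittered for registration (the landmark-
    identification error that dominates the 3P control), but measurements
    are taken at the exact duplicated coordinates.
    """
    acc_rows, prec_rows = [], []
    reports = {"errors": [], "patients": {}}
    for pat in range(config.n_patients):
        spec = replace(config.phantom, seed=_seed(config.master_seed, pat, 1))
        vol0, truth, atlas = build_phantom(spec)
        mesh0 = _prepare_mesh(vol0, config)
        rng = np.random.default_rng(_seed(config.master_seed, pat, 3))
        base = RigidTransform.random(
            rng, spec.rescan_rotation_max_deg, spec.rescan_translation_max_mm
        )
        c = mesh0.vertices.mean(axis=0)
        disp = RigidTransform(base.rotation, c - base.rotation @ c + base.translation)
        mesh1 = mesh0.transformed(disp)
        lm_exact = truth.landmarks_t0.transformed(disp)
        atlas1 = atlas.transformed(disp)
        reports["patients"][pat] = {
            "displacement_rotation_deg": disp.rotation_angle_deg(),
            "faces": mesh0.n_faces,
        }
        lm0_pick, atlas0_pick = jitter_operator(
            truth.landmarks_t0, atlas, config.operator_jitter_sd_mm,
            np.random.default_rng(_seed(config.master_seed, pat, 4)),
            mesh=mesh0, region_fraction=config.region_jitter_fraction,
        )
        lm1_pick, atlas1_pick = jitter_operator(
            lm_exact, atlas1, config.operator_jitter_sd_mm,
            np.random.default_rng(_seed(config.master_seed, pat, 5)),
            mesh=mesh1, region_fraction=config.region_jitter_fraction,
        )
        b0 = Bundle(mesh0, lm0_pick, atlas0_pick)
        b1 = Bundle(mesh1, lm1_pick, atlas1_pick)
        meta = dict(mesh0=mesh0, mesh1=mesh1)
        for tech in config.techniques:
            key = dict(patient=pat, technique=tech, operator=1, session=1)
            cell_seed = _seed(config.master_seed, pat, 6, list(TECHNIQUES).index(tech))
            try:
                tf, rep = superimpose(tech, b0, b1, replace(config.icp, seed=cell_seed))
                acc_row, p_rows = _measure_cell(
                    tech, tf, rep, pat, meta, truth.landmarks_t0, lm_exact, cell_seed
                )
            except Exception as exc:
                log.warning("control cell %s failed: %s", key, exc)
                reports["errors"].append({**key, "error": str(exc)})
                continue
            acc_rows.append({**key, "unit": "fiducials", **acc_row})
            for pr in p_rows:
                prec_rows.append({**key, **pr})
    return pd.DataFrame(acc_rows), pd.DataFrame(prec_rows), reports


# ---------------------------------------------------------------------------
# statistics over the measurement tables
# ---------------------------------------------------------------------------


def _active_factors(table: pd.DataFrame, names) -> list:
    return [n for n in names if n in table.columns and table[n].nunique() > 1]


def run_statistics(accuracy: pd.DataFrame, precision: pd.DataFrame,
                   n_perm: int = 9999, seed: int = 0) -> dict:
    """The study's inference battery: crossed permutational MANOVA on
    accuracy (technique x operator x session) and precision (technique x
    point x operator x session), pairwise technique contrasts, dispersion
    homogeneity, and agreement of each technique with the gold standard."""
    from .stats import UnbalancedDesignError

    out = {}
    if len(accuracy):
        fac = _active_factors(accuracy, ["technique", "operator", "session"])
        try:
            out["permanova_accuracy"] = permanova(
                accuracy, fac, response="D",
                random_factors=[f for f in fac if f == "operator"],
                n_perm=n_perm, seed=seed,
            )
        except UnbalancedDesignError as exc:
            log.warning("accuracy PERMANOVA skipped: %s", exc)
        if accuracy["technique"].nunique() > 1:
            out["pairwise_accuracy"] = pairwise_posthoc(
                accuracy, "technique", n_perm=n_perm, seed=seed
            )
            f, p = permdisp(accuracy, "technique", n_perm=n_perm, seed=seed)
            out["permdisp_accuracy"] = {"F": f, "p": p, "df": accuracy["technique"].nunique() - 1}
    if len(precision):
        fac = _active_factors(precision, ["technique", "unit", "operator", "session"])
        try:
            out["permanova_precision"] = permanova(
                precision, fac, response="D",
                random_factors=[f for f in fac if f == "operator"],
                n_perm=n_perm, seed=seed,
            )
        except UnbalancedDesignError as exc:
            log.warning("precision PERMANOVA skipped: %s", exc)
        # agreement with the gold standard on measured structural change
        if GOLD_STANDARD in set(precision["technique"]):
            keys = ["patient", "operator", "session", "unit"]
            ref = precision[precision.technique == GOLD_STANDARD].set_index(keys)["D"]
            agreements = {}
            for tech in sorted(set(precision["technique"]) - {GOLD_STANDARD}):
                alt = precision[precision.technique == tech].set_index(keys)["D"]
                common = ref.index.intersection(alt.index)
                if len(common) >= 2:
                    agreements[tech] = bland_altman(
                        ref.loc[common].to_numpy(), alt.loc[common].to_numpy(),
                        labels=[str(i) for i in common],
                    )
            out["agreement"] = agreements
    return out


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------


def _quantile_cell(values) -> str:
    med = np.median(values)
    q1, q3 = np.quantile(values, [0.25, 0.75], method="weibull")
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def make_report(tables: dict, stats_results: dict, outdir, deviation_pairs=None) -> list:
    """Write the study artefacts (TSV tables, difference plots, deviation
    meshes) under ``outdir``; returns the list of written paths. Empty
    tables produce explicit 'no data' placeholders."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_tsv(name, df):
        path = outdir / name
        if df is None or len(df) == 0:
            path.write_text("# no data\n")
        else:
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(str(path))

    for name in ("accuracy", "precision", "control_accuracy", "control_precision"):
        if name in tables:
            _write_tsv(f"{name}.tsv", tables[name])

    acc = tables.get("accuracy")
    if acc is not None and len(acc):
        pivot = (
            acc.groupby(["operator", "technique"])["D"]
            .apply(_quantile_cell)
            .unstack("technique")
        )
        path = outdir / "accuracy_by_operator_technique.tsv"
        pivot.to_csv(path, sep="\t")
        written.append(str(path))
    else:
        path = outdir / "accuracy_by_operator_technique.tsv"
        path.write_text("# no data\n")
        written.append(str(path))

    for key in ("permanova_accuracy", "permanova_precision"):
        if key in stats_results:
            _write_tsv(f"{key}.tsv", stats_results[key].table)
    if "pairwise_accuracy" in stats_results:
        _write_tsv("pairwise_accuracy.tsv", stats_results["pairwise_accuracy"])
    if "permdisp_accuracy" in stats_results:
        _write_tsv(
            "permdisp_accuracy.tsv", pd.DataFrame([stats_results["permdisp_accuracy"]])
        )

    if "agreement" in stats_results:
        rows = []
        for tech, summ in stats_results["agreement"].items():
            rows.append(
                dict(
                    technique=tech, n=len(summ.differences), median=summ.median,
                    iqr_low=summ.iqr[0], iqr_high=summ.iqr[1],
                    ci95_low=summ.ci95_median[0], ci95_high=summ.ci95_median[1],
                    trend_rho=summ.trend_rank_correlation,
                )
            )
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(summ.means, summ.differences, s=12, alpha=0.7)
            ax.axhline(summ.median, color="k", lw=1)
            for q in summ.iqr:
                ax.axhline(q, color="k", lw=0.8, ls="--")
            ax.set_xlabel("mean of methods (mm)")
            ax.set_ylabel(f"{tech} − gold standard (mm)")
            ax.set_title(f"Difference plot: {tech} vs gold standard")
            fig.tight_layout()
            p = outdir / f"difference_plot_{tech}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(str(p))
        _write_tsv("agreement.tsv", pd.DataFrame(rows))

    if deviation_pairs:
        for name, (result_mesh, reference_mesh) in deviation_pairs.items():
            colored = deviation_field(result_mesh, reference_mesh, cap_mm=2.0)
            stl_path = outdir / f"superimposed_{name}.stl"
            write_stl(colored, stl_path, mode="binary")
            scal_path = outdir / f"superimposed_{name}_deviation.tsv"
            pd.DataFrame({"signed_deviation_mm": colored.vertex_scalars}).to_csv(
                scal_path, sep="\t", index=False, float_format="%.5g"
            )
            written += [str(stl_path), str(scal_path)]

    manifest = outdir / "manifest.json"
    meta = {
        "package": "cranioreg",
        "version": _pkg_version,
        "files": sorted(written),
    }
    if "config" in tables:
        meta["config"] = tables["config"]
    manifest.write_text(json.dumps(meta, indent=2, default=str))
    written.append(str(manifest))
    for pth in written:
        log.info("wrote %s", pth)
    return written


def config_as_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    return d
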