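"""Study orchestration: configuration, the nine-case sweep, and reporting.

A :class:`RunConfig` bundles everything a run needs (geometry, materials,
scenario selection, solver and optics settings) and round-trips through a
YAML file whose keys carry explicit unit suffixes.  :func:`run_study`
executes the full band-width x IOP x tightening sweep — prestressing once
per IOP and reusing the prestrain across bandwidths — and emits the
scenario table; :func:`analyze` turns any such table (simulated or the
bundled reference table) into per-bandwidth statistics, tightening
power-law fits and extrapolations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import MaterialParams, TISSUE_REGISTRY, registry_from_config, registry_to_config
from .fem import MembraneSystem, SolverSettings
from .geometry import (
    BANDWIDTHS_MM,
    EyeGeometryConfig,
    IOPS_MMHG,
    TIGHTENING_LEVELS_PCT,
    base_cases,
    build_eye_mesh,
)
from .optics import (
    OpticsConfig,
    evaluate_fit,
    fit_power_law,
    load_reference_cases,
    myopic_change,
    relative_increment,
    round_reported,
    summarize_by_bandwidth,
)
from .prestress import compute_prestress
from .surgery import BandSpec, simulate_surgery
from .vtkio import write_vtk

__all__ = ["RunConfig", "run_study", "analyze", "build_mesh_summary"]

log = logging.getLogger("sbsim")

#: scenario CSV column order
CSV_COLUMNS = [
    "case_id",
    "IOP_mmHg",
    "bandwidth_mm",
    "tightening_pct",
    "AL_pre_mm",
    "AL_pos_mm",
    "dAL_mm",
    "dD_diopters",
    "max_stress_MPa",
    "max_stress_region",
]


@dataclass
class RunConfig:
    """Fully serialisable description of one study run."""

    geometry: EyeGeometryConfig = field(default_factory=EyeGeometryConfig)
    materials: dict[str, MaterialParams] = field(default_factory=lambda: dict(TISSUE_REGISTRY))
    iops_mmHg: tuple = IOPS_MMHG
    bandwidths_mm: tuple = BANDWIDTHS_MM
    tightening_pcts: tuple = TIGHTENING_LEVELS_PCT
    surplus_cut_mm: float = 10.0
    band_center_mm: float = 12.5
    resolution: float = 1.0
    solver: SolverSettings = field(default_factory=SolverSettings)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    out_dir: str = "sbsim_out"
    seed: int = 0  # used only by noise studies; the mechanics path is deterministic
    export_vtk: bool = False

    def to_dict(self) -> dict:
        g = self.geometry
        return {
            "geometry": {
                "cornea_semiaxes_mm": list(g.cornea_semiaxes),
                "corneal_diameters_mm": list(g.corneal_diameters),
                "central_corneal_thickness_mm": g.central_corneal_thickness,
                "globe_dimensions_mm": list(g.globe_dimensions),
                "lens_radii_mm": list(g.lens_radii),
                "scleral_thickness_profile_mm": [list(a) for a in g.scleral_thickness_profile],
                "limbus_width_mm": g.limbus_width,
                "nerve_patch_radius_mm": g.nerve_patch_radius,
                "lens_diameter_mm": g.lens_diameter,
                "anterior_chamber_depth_mm": g.anterior_chamber_depth,
                "lens_capsule_thickness_mm": g.lens_capsule_thickness,
                "fine_window_mm": list(g.fine_window),
                "ocular_rigidity_MPa_per_mm3": g.ocular_rigidity,
            },
            "materials": registry_to_config(self.materials),
            "study": {
                "iops_mmHg": list(self.iops_mmHg),
                "bandwidths_mm": list(self.bandwidths_mm),
                "tightening_pcts": list(self.tightening_pcts),
                "surplus_cut_mm": self.surplus_cut_mm,
                "band_center_mm": self.band_center_mm,
                "resolution": self.resolution,
            },
            "solver": dataclasses.asdict(self.solver),
            "optics": {"n1": self.optics.n1, "D1_diopters": self.optics.D1, "D2_diopters": self.optics.D2, "d_mm": self.optics.d},
            "out_dir": self.out_dir,
            "seed": self.seed,
            "export_vtk": self.export_vtk,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        g = d.get("geometry", {})
        geometry = EyeGeometryConfig(
            cornea_semiaxes=tuple(g.get("cornea_semiaxes_mm", (10.43, 10.27, 14.26))),
            corneal_diameters=tuple(g.get("corneal_diameters_mm", (11.26, 11.51))),
            central_corneal_thickness=g.get("central_corneal_thickness_mm", 0.550),
            globe_dimensions=tuple(g.get("globe_dimensions_mm", (25.43, 25.76, 24.86))),
            lens_radii=tuple(g.get("lens_radii_mm", (11.0, -6.5))),
            scleral_thickness_profile=tuple(
                tuple(a) for a in g.get("scleral_thickness_profile_mm", ((0.0, 0.80), (12.5, 0.49), (30.0, 1.00)))
            ),
            limbus_width=g.get("limbus_width_mm", 1.0),
            nerve_patch_radius=g.get("nerve_patch_radius_mm", 1.0),
            lens_diameter=g.get("lens_diameter_mm", 9.0),
            anterior_chamber_depth=g.get("anterior_chamber_depth_mm", 3.0),
            lens_capsule_thickness=g.get("lens_capsule_thickness_mm", 0.5),
            fine_window=tuple(g.get("fine_window_mm", (10.25, 14.75))),
            ocular_rigidity=g.get("ocular_rigidity_MPa_per_mm3", 3.3e-6),
        )
        materials = registry_from_config(d["materials"]) if "materials" in d else dict(TISSUE_REGISTRY)
        s = d.get("study", {})
        o = d.get("optics", {})
        return cls(
            geometry=geometry,
            materials=materials,
            iops_mmHg=tuple(s.get("iops_mmHg", IOPS_MMHG)),
            bandwidths_mm=tuple(s.get("bandwidths_mm", BANDWIDTHS_MM)),
            tightening_pcts=tuple(s.get("tightening_pcts", TIGHTENING_LEVELS_PCT)),
            surplus_cut_mm=s.get("surplus_cut_mm", 10.0),
            band_center_mm=s.get("band_center_mm", 12.5),
            resolution=s.get("resolution", 1.0),
            solver=SolverSettings(**d.get("solver", {})),
            optics=OpticsConfig(
                n1=o.get("n1", 1.336), D1=o.get("D1_diopters"), D2=o.get("D2_diopters"), d=o.get("d_mm")
            ),
            out_dir=d.get("out_dir", "sbsim_out"),
            seed=d.get("seed", 0),
            export_vtk=d.get("export_vtk", False),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_mesh_summary(config: RunConfig, out_path=None) -> dict:
    """Build the mesh, optionally export it to VTK, and return counts."""
    mesh = build_eye_mesh(config.geometry, config.resolution)
    if out_path is not None:
        write_vtk(
            out_path,
            mesh.nodes,
            mesh.elements,
            point_data={"thickness_mm": mesh.thickness, "arc_from_limbus_mm": mesh.arc_from_limbus},
            cell_data={"region": mesh.element_region, "fiber_m": mesh.fiber_m, "fiber_n": mesh.fiber_n},
        )
    from .geometry import compute_axial_length

    return {
        "n_nodes": mesh.n_nodes,
        "n_elements": int(mesh.elements.shape[0]),
        "axial_length_mm": compute_axial_length(mesh),
        "euler_characteristic_globe": mesh.euler_characteristic("globe"),
        "regions": {r: int((mesh.element_region == r).sum()) for r in np.unique(mesh.element_region)},
    }


def run_study(
    config: RunConfig,
    cases: list[int] | None = None,
    mesh=None,
    prestrain_cache: dict | None = None,
) -> pd.DataFrame:
    """Execute the scenario sweep and return the Tables-shaped DataFrame.

    ``cases`` restricts to a subset of case ids (1-9).  Prestress is
    computed once per IOP (reusable via ``prestrain_cache``); each
    (bandwidth, IOP) pair then runs one displacement continuation through
    all tightening levels.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = mesh or build_eye_mesh(config.geometry, config.resolution)
    cache = prestrain_cache if prestrain_cache is not None else {}
    rows = []
    all_cases = [
        (cid, bw, iop)
        for cid, bw, iop in base_cases()
        if bw in config.bandwidths_mm and iop in config.iops_mmHg
    ]
    if cases is not None:
        all_cases = [c for c in all_cases if c[0] in cases]
    system = MembraneSystem(mesh, config.materials)
    for cid, bw, iop in all_cases:
        if iop not in cache:
            t0 = time.time()
            cache[iop] = compute_prestress(
                mesh, iop, config.materials, settings=config.solver, system=system
            )
            log.info(
                "prestress IOP %g mmHg: %d iterations, %.1f s",
                iop,
                len(cache[iop].iteration_history),
                time.time() - t0,
            )
        band = BandSpec(width=bw, center_arc_distance=config.band_center_mm, surplus_cut=config.surplus_cut_mm)
        t0 = time.time()
        results = simulate_surgery(
            mesh,
            config.materials,
            prestrain=cache[iop],
            iop=iop,
            band=band,
            tightening_fractions=[p / 100.0 for p in config.tightening_pcts],
            settings=config.solver,
            system=system,
            keep_states=config.export_vtk,
        )
        log.info("case %d (%.1f mm, %g mmHg): %.1f s", cid, bw, iop, time.time() - t0)
        for res in results:
            res.delta_D = myopic_change(res.AL_pre, res.AL_pos, config.optics.n1)
            rows.append(
                {
                    "case_id": cid,
                    "IOP_mmHg": iop,
                    "bandwidth_mm": bw,
                    "tightening_pct": res.tightening_pct,
                    "AL_pre_mm": res.AL_pre,
                    "AL_pos_mm": res.AL_pos,
                    "dAL_mm": res.delta_AL,
                    "dD_diopters": res.delta_D,
                    "max_stress_MPa": res.max_principal_stress,
                    "max_stress_region": res.max_stress_region,
                }
            )
            if config.export_vtk and res.state is not None:
                write_vtk(
                    out / f"case{cid}_t{int(res.tightening_pct)}.vtk",
                    mesh.nodes + res.state.displacements,
                    mesh.elements,
                    point_data={"displacement_mm": res.state.displacements},
                    cell_data={
                        "max_principal_stress_MPa": res.state.max_principal_stress,
                        "log_strain": res.state.log_strain,
                        "region": mesh.element_region,
                    },
                )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(out / "scenarios.csv", index=False)
    return df


def analyze(df: pd.DataFrame | str, n1: float = 1.336) -> dict:
    """Per-bandwidth statistics, power-law fits and 125% extrapolations.

    ``df`` is a scenario table from :func:`run_study` or the string
    ``"fixtures"`` for the bundled reference table.
    """
    if isinstance(df, str):
        if df != "fixtures":
            df = pd.read_csv(df)
            if df.empty:
                raise ValueError("scenario table is empty")
        else:
            ref = load_reference_cases()
            rows = []
            for _, r in ref.iterrows():
                for pct, col in ((33.0, "dD33_D"), (67.0, "dD67_D"), (100.0, "dD100_D")):
                    rows.append(
                        {
                            "case_id": r.case_id,
                            "IOP_mmHg": r.iop_mmHg,
                            "bandwidth_mm": r.bandwidth_mm,
                            "tightening_pct": pct,
                            "AL_pre_mm": r.AL_pre_mm,
                            "AL_pos_mm": r.AL_pos_mm if pct == 100.0 else np.nan,
                            "dAL_mm": r.dAL_mm if pct == 100.0 else np.nan,
                            "dD_diopters": r[col],
                        }
                    )
            df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("scenario table is empty")

    full = df[df.tightening_pct == 100.0].rename(columns={"dAL_mm": "dAL_mm", "dD_diopters": "dD_D"})
    summary = summarize_by_bandwidth(full[["bandwidth_mm", "dAL_mm", "dD_D"]])

    report = {"per_bandwidth": {}, "n1": n1}
    for bw in sorted(df.bandwidth_mm.unique(), reverse=True):
        sub = df[df.bandwidth_mm == bw]
        means = sub.groupby("tightening_pct")["dD_diopters"].mean()
        entry = {
            "mean_dAL_mm": None if bw not in summary.index else round(float(summary.loc[bw, "mean_dAL_mm"]), 4),
            "sd_dAL_mm": None if bw not in summary.index else round(float(summary.loc[bw, "sd_dAL_mm"]), 4),
            "mean_dD_D": round_reported(float(means.loc[100.0])) if 100.0 in means.index else None,
            "sd_dD_D": None if bw not in summary.index else round(float(summary.loc[bw, "sd_dD_D"]), 4),
            "mean_dD_by_tightening": {float(k): round(float(v), 4) for k, v in means.items()},
        }
        if len(means) >= 3:
            fit = fit_power_law(means.index.to_numpy(), means.to_numpy())
            d125 = evaluate_fit(fit, 125.0)
            entry["power_fit"] = {"a": fit.a, "b": fit.b, "c": fit.c, "rmse_D": fit.rmse}
            entry["dD_at_125pct_D"] = round_reported(d125)
            if 100.0 in means.index:
                entry["increment_100_to_125_pct"] = round(
                    relative_increment(float(means.loc[100.0]), d125), 1
                )
        report["per_bandwidth"][float(bw)] = entry
    return report
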