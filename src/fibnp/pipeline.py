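"""End-to-end orchestration: generate → analyze → report.

A :class:`RunConfig` (YAML-round-trippable) fixes every seed and parameter;
:func:`run_pipeline` builds the synthetic fibril (and optionally poses a
nanoparticle next to it), synthesizes a noisy trajectory, runs the twist /
contact / surface-area / energy analyses on the trajectory tail, writes every
intermediate artifact, and returns an :class:`AnalysisReport` that serializes
deterministically (no timestamps), so identical configs give byte-identical
reports.

The twist statistic is cheap and uses every requested frame; the SASA,
energy and contact stages accept a frame stride so frame-averaged summaries
stay affordable at desk scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .energy import InteractionReport, trajectory_energy
from .io import write_structure, write_trajectory
from .model import (NonbondedParams, StructureModel, Trajectory, concat_models,
                    intersection, select, union)
from .surface import BindingProfile, ContactAreaResult, binding_profile, contact_area
from .synthetic import (FibrilSpec, NPSpec, build_fibril, build_nanoparticle,
                        place_near, synthesize_trajectory)
from .twist import TwistReport, compute_twist_report

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "summarize",
           "pose_selection"]


@dataclass
class TrajectoryConfig:
    n_frames: int = 500
    noise_sigma: float = 0.0
    rng_seed: int = 0
    frame_dt: float = 10.0


@dataclass
class PlacementConfig:
    """Where to pose the nanoparticle against the fibril.

    ``target`` is "acidic_face" (Glu22/Asp23 sidechain beads of the mid
    peptides — the β-sheet nesting site), "tip" (the terminal peptide's
    Lys28 bead), or "custom" with an explicit chain/residue window.
    """

    target: str = "acidic_face"
    gap: float = 3.0
    chain: str | None = None
    residue_range: tuple[int, int] | None = None


@dataclass
class AnalysisConfig:
    dielectric: float = 78.5
    lj_cutoff: float = 10.0
    contact_cutoff: float = 5.0
    probe_radius: float = 1.4
    sasa_points: int = 500
    rng_seed: int = 0
    coulomb_cutoff: float | None = None
    inner_range: tuple[int, int] = (4, 25)
    last_n_frames: int = 500
    bin_width: float = 1.0
    sasa_stride: int = 20
    energy_stride: int = 20
    contact_stride: int = 5

    def nonbonded(self) -> NonbondedParams:
        return NonbondedParams(
            dielectric=self.dielectric, lj_cutoff=self.lj_cutoff,
            contact_cutoff=self.contact_cutoff, probe_radius=self.probe_radius,
            sasa_points=self.sasa_points, rng_seed=self.rng_seed,
            coulomb_cutoff=self.coulomb_cutoff,
        )


@dataclass
class RunConfig:
    """Full description of one pipeline run; round-trips through YAML."""

    fibril: FibrilSpec = field(default_factory=FibrilSpec)
    nanoparticle: NPSpec | None = None
    np_recipe: str | None = None
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def resolve_np(self) -> NPSpec | None:
        if self.nanoparticle is not None:
            return self.nanoparticle
        if self.np_recipe is not None:
            return NPSpec.from_recipe(self.np_recipe)
        return None

    # ------------------------------------------------------------- yaml io
    def to_dict(self) -> dict:
        d = {
            "fibril": asdict(self.fibril),
            "nanoparticle": None if self.nanoparticle is None else asdict(self.nanoparticle),
            "np_recipe": self.np_recipe,
            "placement": asdict(self.placement),
            "trajectory": asdict(self.trajectory),
            "analysis": asdict(self.analysis),
        }
        for key in ("placement", "analysis"):
            for k, v in d[key].items():
                if isinstance(v, tuple):
                    d[key][k] = list(v)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def _tup(x):
            return None if x is None else tuple(x)
        placement = d.get("placement", {})
        placement = PlacementConfig(
            target=placement.get("target", "acidic_face"),
            gap=placement.get("gap", 3.0),
            chain=placement.get("chain"),
            residue_range=_tup(placement.get("residue_range")),
        )
        analysis = dict(d.get("analysis", {}))
        if "inner_range" in analysis:
            analysis["inner_range"] = tuple(analysis["inner_range"])
        return cls(
            fibril=FibrilSpec(**d.get("fibril", {})),
            nanoparticle=(None if d.get("nanoparticle") is None
                          else NPSpec(**d["nanoparticle"])),
            np_recipe=d.get("np_recipe"),
            placement=placement,
            trajectory=TrajectoryConfig(**d.get("trajectory", {})),
            analysis=AnalysisConfig(**analysis),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def pose_selection(fibril: StructureModel, placement: PlacementConfig) -> np.ndarray:
    """Atom indices of the placement target on the fibril."""
    cb = np.nonzero(fibril.names == "CB")[0]
    if placement.target == "acidic_face":
        pf = fibril.protofilaments[0]
        mid = pf[len(pf) // 2 - 2: len(pf) // 2 + 3]
        sels = [
            intersection(select(fibril, chain=fibril.peptides[p].chain_id,
                                residue_seq=(22, 23)), cb)
            for p in mid
        ]
        return union(*sels)
    if placement.target == "tip":
        top = fibril.peptides[fibril.protofilaments[0][-1]]
        return intersection(select(fibril, chain=top.chain_id, residue_seq=28), cb)
    if placement.target == "custom":
        if placement.chain is None or placement.residue_range is None:
            raise ValueError("custom placement needs chain and residue_range")
        return select(fibril, chain=placement.chain,
                      residue_seq=placement.residue_range)
    raise ValueError(f"unknown placement target {placement.target!r}")


@dataclass
class AnalysisReport:
    """Aggregated stage outputs plus provenance."""

    twist: list[TwistReport]
    contacts: BindingProfile | None
    areas: list[ContactAreaResult]
    energies: InteractionReport | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "twist": [t.to_dict() for t in self.twist],
            "contacts": None if self.contacts is None else self.contacts.to_dict(),
            "areas": [a.to_dict() for a in self.areas],
            "energies": None if self.energies is None else self.energies.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _stage(log: list[str], name: str, path: Path | None = None) -> None:
    entry = name if path is None else f"{name} -> {path.name}"
    log.append(entry)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> AnalysisReport:
    """Run generate → analyze → report; every artifact lands in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    params = config.analysis.nonbonded()

    def fail(stage: str, exc: Exception) -> Exception:
        err = RuntimeError(f"pipeline stage '{stage}' failed: {exc}")
        err.__cause__ = exc
        return err

    # ---- generation ------------------------------------------------------
    try:
        fibril = build_fibril(config.fibril)
        write_structure(fibril, out / "fibril.pqr")
        _stage(log, "build_fibril", out / "fibril.pqr")
    except Exception as exc:
        raise fail("build_fibril", exc)

    np_spec = config.resolve_np()
    if np_spec is not None:
        try:
            np_model = build_nanoparticle(np_spec)
            target = pose_selection(fibril, config.placement)
            np_model = place_near(np_model, fibril, target, config.placement.gap)
            write_structure(np_model, out / "nanoparticle.pqr")
            system = concat_models([fibril, np_model])
            _stage(log, "build_nanoparticle", out / "nanoparticle.pqr")
        except Exception as exc:
            raise fail("build_nanoparticle", exc)
    else:
        np_model = None
        system = fibril

    try:
        traj = synthesize_trajectory(
            system, config.trajectory.n_frames, config.trajectory.noise_sigma,
            rng_seed=config.trajectory.rng_seed,
            frame_dt=config.trajectory.frame_dt,
        )
        write_trajectory(traj, out / "trajectory.xyz")
        _stage(log, "synthesize_trajectory", out / "trajectory.xyz")
    except Exception as exc:
        raise fail("synthesize_trajectory", exc)

    # ---- analyses --------------------------------------------------------
    a = config.analysis
    try:
        twist_reports = [
            compute_twist_report(traj, protofilament=pf,
                                 inner_range=a.inner_range,
                                 last_n_frames=a.last_n_frames,
                                 bin_width=a.bin_width)
            for pf in range(len(system.protofilaments))
        ]
        _write_twist_tsv(twist_reports, out / "twist.tsv")
        _stage(log, "twist_analysis", out / "twist.tsv")
    except Exception as exc:
        raise fail("twist_analysis", exc)

    contacts = None
    areas: list[ContactAreaResult] = []
    energies = None
    if np_model is not None:
        np_sel = select(system, role_tag="nanoparticle")
        fib_sel = select(system, role_tag="fibril")
        beta_sel = intersection(fib_sel, select(system, residue_seq=(12, 40)))
        try:
            pep_sels = [
                intersection(system.peptide_atom_indices(system.peptides[p]), fib_sel)
                for pf in system.protofilaments for p in pf
            ]
            contacts = binding_profile(system, pep_sels, np_sel, traj, params,
                                       last_n_frames=a.last_n_frames,
                                       frame_stride=a.contact_stride)
            _stage(log, "binding_profile")
        except Exception as exc:
            raise fail("binding_profile", exc)
        try:
            areas = [
                contact_area(np_sel, fib_sel, traj, params,
                             last_n_frames=a.last_n_frames,
                             frame_stride=a.sasa_stride, context_label="fibril"),
                contact_area(np_sel, beta_sel, traj, params,
                             last_n_frames=a.last_n_frames,
                             frame_stride=a.sasa_stride,
                             context_label="beta_sheet"),
            ]
            _stage(log, "contact_area")
        except Exception as exc:
            raise fail("contact_area", exc)
        try:
            energies = trajectory_energy(system, np_sel, fib_sel, traj, params,
                                         last_n_frames=a.last_n_frames,
                                         frame_stride=a.energy_stride)
            energies.per_frame.to_csv(out / "energies.tsv", sep="\t", index=False)
            _stage(log, "trajectory_energy", out / "energies.tsv")
        except Exception as exc:
            raise fail("trajectory_energy", exc)

    provenance = {
        "fibnp_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": log,
    }
    report = AnalysisReport(twist=twist_reports, contacts=contacts,
                            areas=areas, energies=energies,
                            provenance=provenance)
    report.to_json(out / "report.json")
    (out / "summary.txt").write_text(summarize(report))
    config.to_yaml(out / "config.yaml")
    return report


def _write_twist_tsv(reports: list[TwistReport], path: Path) -> None:
    lines = ["protofilament\tframe\tpair\tangle_deg"]
    for pf, rep in enumerate(reports):
        for fi in range(rep.pair_angles.shape[0]):
            for pi in range(rep.m):
                lines.append(f"{pf}\t{fi}\t{pi}\t{rep.pair_angles[fi, pi]:.6f}")
    path.write_text("\n".join(lines) + "\n")


def summarize(report: AnalysisReport) -> str:
    """Human-readable summary table (angles in degrees, areas in nm²,
    energies in kcal/mol)."""
    lines = ["== fibnp analysis summary =="]
    for pf, t in enumerate(report.twist):
        bp = t.bin_percentages
        lines.append(
            f"twist[pf{pf}]: theta_twist = {t.theta_twist:.2f} deg  "
            f"(m = {t.m} pairs, {t.frames_used} frames, "
            f"{t.pair_angles.size} angles)"
        )
        lines.append(
            f"  bins: <10deg {bp['<10']:.2f}%  |  10-20deg {bp['10-20']:.2f}%"
            f"  |  >=20deg {bp['>=20']:.2f}%"
        )
    for area in report.areas:
        lines.append(
            f"contact area [{area.context_label}]: "
            f"{area.contact_area / 100.0:.3f} nm^2 "
            f"(SASA alone {area.sasa_alone / 100.0:.3f}, "
            f"in context {area.sasa_in_context / 100.0:.3f} nm^2, "
            f"mc_se {area.mc_se / 100.0:.3f} nm^2)"
        )
    if report.contacts is not None:
        top = np.argsort(report.contacts.means)[::-1][:5]
        desc = ", ".join(
            f"pep{int(i) + 1}: {report.contacts.means[i]:.1f}" for i in top
        )
        lines.append(f"heavy-atom contacts (top peptides): {desc}")
    if report.energies is not None:
        e = report.energies
        lines.append(
            f"energies: coulomb {e.coulomb:.1f}  lj {e.lj:.1f}  "
            f"total {e.total:.1f} kcal/mol "
            f"(dielectric {e.dielectric}, LJ cutoff {e.lj_cutoff} A, "
            f"{e.frames_used} frames)"
        )
    return "\n".join(lines) + "\n"
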