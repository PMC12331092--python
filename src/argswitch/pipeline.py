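"""Config-driven orchestration of the full analysis chain.

A run config is one YAML file; every stage reads its section, writes tidy
TSV/JSON into the output directory, and registers each artifact in a
manifest with a content hash.  Reports are deterministic: two runs with the
same config and seeds produce byte-identical JSON (no timestamps).

The default contact set is the five phosphopeptide–arrestin pairs of the
intermediate-state interface: pS350–R77, pS350–R148, pS350–R166, pT352–R166
(site I) and E358–R394 (site II), as min-over-group salt bridges between
phosphate/carboxylate oxygens and guanidinium nitrogens at a 4.0 Å cutoff.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import metrics, stats
from .clustering import ClusterParams, pairwise_rmsd_matrix, qt_cluster
from .errors import ArgSwitchError, EmptyInputError
from .itc import ITCExperiment, compare_models, read_isotherm_csv
from .metrics import (
    ContactDefinition,
    classify_states,
    contact_fraction,
    distance_series,
    polar_core_series,
    series_to_frame,
)
from .stats import hdx_classify_regions, hdx_compare_peptide, mann_whitney_u, read_hdx_csv
from .synth import SwitchSimParams, gen_switch_trajectory
from .traj import ReplicateSet, Topology, Trajectory, load_topology, load_trajectory, select_atoms

logger = logging.getLogger("argswitch")

__all__ = [
    "RunConfig",
    "load_config",
    "default_contacts",
    "run_switch_analysis",
    "run_itc",
    "run_hdx",
]

#: (name, acidic residue, basic residue) of the standard interface contacts.
STANDARD_CONTACT_PAIRS = (
    ("pS350-R77", 350, 77),
    ("pS350-R148", 350, 148),
    ("pS350-R166", 350, 166),
    ("pT352-R166", 352, 166),
    ("E358-R394", 358, 394),
)

_ACIDIC_ATOMS = "O1P O2P O3P OD1 OD2 OE1 OE2"
_BASIC_ATOMS = "NH1 NH2 NE NZ"


@dataclass
class RunConfig:
    """Validated view of the YAML run configuration."""

    raw: dict
    path: Path | None = None

    def section(self, name: str) -> dict:
        if name not in self.raw:
            raise ArgSwitchError(f"config has no {name!r} section")
        return self.raw[name]

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def out_dir(self) -> Path:
        return Path(self.raw.get("out_dir", "argswitch_out"))


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ArgSwitchError(f"{path}: config must be a YAML mapping")
    # round-trip invariance: serialisation must reproduce the parsed tree
    assert yaml.safe_load(yaml.safe_dump(raw)) == raw
    return RunConfig(raw=raw, path=Path(path))


def default_contacts(
    topology: Topology, cutoff: float = metrics.SALT_BRIDGE_CUTOFF
) -> list[ContactDefinition]:
    """The five standard interface salt bridges resolvable in ``topology``."""
    contacts = []
    for name, acid, base in STANDARD_CONTACT_PAIRS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel_a = select_atoms(topology, f"resid {acid} and name {_ACIDIC_ATOMS}")
            sel_b = select_atoms(topology, f"resid {base} and name {_BASIC_ATOMS}")
        if len(sel_a) == 0 or len(sel_b) == 0:
            logger.info("contact %s not resolvable in this topology; skipped", name)
            continue
        contacts.append(
            ContactDefinition(
                name=name, sel_a=sel_a, sel_b=sel_b, mode="min-group", cutoff=cutoff
            )
        )
    return contacts


# ---------------------------------------------------------------------------
# Output bookkeeping
# ---------------------------------------------------------------------------

class _Bundle:
    """Collects output files and writes the content-hash manifest."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        out_dir.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, str] = {}

    def write_json(self, name: str, obj) -> Path:
        path = self.out_dir / name
        payload = json.dumps(obj, indent=2, sort_keys=True, default=_jsonable)
        path.write_text(payload + "\n")
        self._register(path)
        return path

    def write_text(self, name: str, text: str) -> Path:
        path = self.out_dir / name
        path.write_text(text)
        self._register(path)
        return path

    def write_table(self, name: str, df) -> Path:
        path = self.out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self._register(path)
        return path

    def _register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = digest

    def finish(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(
            json.dumps({"files": self.files}, indent=2, sort_keys=True) + "\n"
        )
        return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Trajectory loading (files or synthetic)
# ---------------------------------------------------------------------------

def _load_condition(name: str, cfg: dict, base_seed: int) -> ReplicateSet:
    window = cfg.get("window", "all")
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        n_replicates = int(syn.pop("n_replicates", 1))
        seed0 = int(syn.pop("seed", base_seed))
        trajs = []
        for r in range(n_replicates):
            params = SwitchSimParams(seed=seed0 + r, **syn)
            traj, _ = gen_switch_trajectory(params)
            traj.replicate_id = f"{name}-rep{r + 1}"
            traj.condition = name
            trajs.append(traj)
        return ReplicateSet(trajectories=trajs, analysis_window=window)
    paths = cfg.get("trajectories", [])
    if not paths:
        raise EmptyInputError(
            f"condition {name!r}: no trajectories given (and no synthetic block)"
        )
    topology = load_topology(cfg.get("topology", paths[0]))
    trajs = [
        load_trajectory(
            p, topology, format=cfg.get("format", "pdb-multimodel"),
            replicate_id=f"{name}-rep{i + 1}", condition=name,
        )
        for i, p in enumerate(paths)
    ]
    return ReplicateSet(trajectories=trajs, analysis_window=window)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_switch_analysis(config: RunConfig) -> dict:
    """Distance series → contact fractions → clustering → states → condition stats."""
    cfg = config.section("switch")
    out = _Bundle(config.out_dir / "switch")
    contact_cutoff = float(cfg.get("contact_cutoff_A", metrics.SALT_BRIDGE_CUTOFF))
    cluster_cutoff = float(cfg.get("cluster_cutoff_A", 3.7))
    threshold = float(cfg.get("state_threshold_A", metrics.SWITCH_STATE_THRESHOLD))

    conditions: dict[str, ReplicateSet] = {}
    for cond_cfg in cfg.get("conditions", []):
        name = cond_cfg["name"]
        logger.info("loading condition %s", name)
        conditions[name] = _load_condition(name, cond_cfg, config.seed)
    if not conditions:
        raise EmptyInputError("switch analysis: no conditions configured")

    report: dict = {"conditions": {}, "comparisons": {}}
    polar_by_condition: dict[str, np.ndarray] = {}
    all_series = []
    contact_rows = []
    cluster_rows = []
    for name, reps in conditions.items():
        windowed = reps.windowed()
        topology = windowed[0].topology
        contacts = default_contacts(topology, cutoff=contact_cutoff)
        cond_report: dict = {"n_replicates": len(windowed), "contacts": {}}

        for contact in contacts:
            series = [distance_series(t, contact) for t in windowed]
            all_series.extend(series)
            frac, per_rep = contact_fraction(series, contact.cutoff)
            n_frames = int(sum(len(s) for s in series))
            cond_report["contacts"][contact.name] = {
                "stability_pct": 100.0 * frac,
                "per_replicate_pct": {k: 100.0 * v for k, v in per_rep.items()},
                "cutoff_A": contact.cutoff,
                "n_frames": n_frames,
            }
            contact_rows.append(
                {
                    "condition": name,
                    "contact_name": contact.name,
                    "cutoff_A": contact.cutoff,
                    "fraction": frac,
                    "n_frames": n_frames,
                }
            )

        polar = [polar_core_series(t) for t in windowed]
        all_series.extend(polar)
        pooled = np.concatenate([s.values for s in polar])
        polar_by_condition[name] = pooled
        states = [classify_states(s, threshold) for s in polar]
        engaged_frac = float(np.mean(np.concatenate([s.engaged for s in states])))
        cond_report["polar_core"] = {
            "mean_distance_A": float(pooled.mean()),
            "box": vars(stats.box_summary(pooled)) | {},
            "engaged_fraction": engaged_frac,
            "threshold_A": threshold,
        }

        # conformer clustering of the switch residue, pooled over replicates
        switch_resid = int(cfg.get("switch_residue", 394))
        sel = select_atoms(topology, f"resid {switch_resid}")
        pooled_coords = np.concatenate([t.coords for t in windowed], axis=0)
        pooled_traj = Trajectory(
            topology=topology, coords=pooled_coords, condition=name
        )
        matrix = pairwise_rmsd_matrix(pooled_traj, sel)
        result = qt_cluster(matrix, ClusterParams(cutoff=cluster_cutoff))
        cond_report["clusters"] = {
            "cutoff_A": cluster_cutoff,
            "clusters": result.summary(),
            "unassigned_pct": result.unassigned_pct,
        }
        cluster_rows.extend(
            {"condition": name, "frame": f, "cluster_id": int(cid)}
            for f, cid in enumerate(result.assignment)
        )
        report["conditions"][name] = cond_report

    names = sorted(polar_by_condition)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = mann_whitney_u(polar_by_condition[a], polar_by_condition[b])
            report["comparisons"][f"{a}_vs_{b}"] = {
                "U": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "n1": res.n1,
                "n2": res.n2,
            }

    import pandas as pd

    out.write_table("distances.tsv", series_to_frame(all_series))
    out.write_table("contact_summary.tsv", pd.DataFrame(contact_rows))
    out.write_table("clusters.tsv", pd.DataFrame(cluster_rows))
    out.write_json("report.json", report)
    out.write_text("summary.txt", _switch_summary_text(report))
    out.finish()
    return report


def _switch_summary_text(report: dict) -> str:
    lines = ["switch analysis summary", "======================="]
    for name, cond in report["conditions"].items():
        pc = cond["polar_core"]
        lines.append(
            f"{name}: polar-core mean {pc['mean_distance_A']:.2f} Å, "
            f"engaged fraction {pc['engaged_fraction']:.3f}"
        )
        for cname, c in cond["contacts"].items():
            lines.append(f"  contact {cname}: {c['stability_pct']:.1f}% stable")
        top = cond["clusters"]["clusters"]
        if top:
            lines.append(
                f"  largest conformer cluster: {top[0]['population_pct']:.1f}% "
                f"(center frame {top[0]['center_frame']})"
            )
    for pair, comp in report["comparisons"].items():
        lines.append(
            f"{pair}: Mann-Whitney U={comp['U']:.1f}, p={comp['p_value']:.3g} "
            f"({comp['method']})"
        )
    return "\n".join(lines) + "\n"


def run_itc(config: RunConfig) -> dict:
    """Fit one- and two-site models to an isotherm and select between them."""
    cfg = config.section("itc")
    out = _Bundle(config.out_dir / "itc")
    exp = ITCExperiment(
        cell_volume_uL=float(cfg.get("cell_volume_uL", 200.0)),
        macromolecule_conc_uM=float(cfg.get("macromolecule_conc_uM", 200.0)),
        syringe_conc_uM=float(cfg.get("syringe_conc_uM", 1000.0)),
        injection_volumes_uL=tuple(
            cfg.get("injection_volumes_uL", [2.5] * int(cfg.get("n_injections", 25)))
        ),
        temperature_K=float(cfg.get("temperature_K", 298.0)),
    )
    if "synthetic" in cfg:
        from .itc import BindingParams
        from .synth import gen_itc_isotherm

        syn = dict(cfg["synthetic"])
        noise = float(syn.pop("noise_sigma", 0.0))
        seed = int(syn.pop("seed", config.seed))
        iso, truth = gen_itc_isotherm(exp, BindingParams(**syn), noise, seed)
    elif "csv" in cfg:
        iso, _ = read_isotherm_csv(cfg["csv"])
        truth = None
    else:
        raise ArgSwitchError("itc section needs either 'csv' or 'synthetic'")

    comparison = compare_models(iso, exp)
    chosen = (
        comparison.two_site if comparison.preferred == "two_site" else comparison.one_site
    )
    report = {
        "preferred_model": comparison.preferred,
        "f_statistic": comparison.f_statistic,
        "p_value": comparison.p_value,
        "no_binding": comparison.no_binding,
        "fit": {
            "model": chosen.model,
            "kd1_uM": chosen.params.kd1,
            "kd2_uM": chosen.params.kd2,
            "dh1_kcal_mol": chosen.params.dh1,
            "dh2_kcal_mol": chosen.params.dh2,
            "n1": chosen.params.n1,
            "n2": chosen.params.n2,
            "baseline": chosen.params.baseline,
            "ssr": chosen.ssr,
            "converged": chosen.converged,
        },
    }
    if truth is not None:
        report["truth"] = truth
    out.write_json("fit_report.json", report)
    out.finish()
    return report


def run_hdx(config: RunConfig) -> dict:
    """Differential-uptake comparison and region classification."""
    cfg = config.section("hdx")
    out = _Bundle(config.out_dir / "hdx")
    state_a = cfg.get("state_a", "apo")
    state_b = cfg.get("state_b", "bound")
    if "synthetic" in cfg:
        from .synth import HDXPeptideSpec, HDXSimParams, gen_hdx_dataset

        syn = cfg["synthetic"]
        specs = tuple(
            HDXPeptideSpec(
                start_res=int(p["start_res"]),
                end_res=int(p["end_res"]),
                n_exchangeable=int(p["n_exchangeable"]),
                k_int=float(p["k_int"]),
                protection={state_a: float(p["P_a"]), state_b: float(p["P_b"])},
            )
            for p in syn["peptides"]
        )
        params = HDXSimParams(
            peptides=specs,
            noise_sigma_Da=float(syn.get("noise_sigma_Da", 0.05)),
            n_replicates=int(syn.get("n_replicates", 3)),
            seed=int(syn.get("seed", config.seed)),
        )
        df, _truth = gen_hdx_dataset(params, states=(state_a, state_b))
        csv_path = out.out_dir / "uptake.csv"
        df.to_csv(csv_path, index=False)
        peptides = read_hdx_csv(str(csv_path))
    elif "csv" in cfg:
        peptides = read_hdx_csv(cfg["csv"])
    else:
        raise ArgSwitchError("hdx section needs either 'csv' or 'synthetic'")

    rows = []
    for p in peptides:
        rows.extend(hdx_compare_peptide(p, state_a, state_b))
    classes = hdx_classify_regions(rows)
    out.write_table("comparison.tsv", stats.comparison_to_frame(rows, classes))
    report = {
        "state_a": state_a,
        "state_b": state_b,
        "classes": classes,
        "n_peptides": len(peptides),
        "n_significant_timepoints": int(sum(r.significant for r in rows)),
    }
    out.write_json("report.json", report)
    out.finish()
    return report
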