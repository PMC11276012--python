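"""Config-driven orchestration: trajectories in, report bundle out.

For every configured *system* (one ligand's topology + replica
trajectories) the pipeline classifies each frame's polar engagement with
the focal residue, then derives category fractions, conditional contact
distances, water-bridge autocorrelation curves and correlation times,
and bridging-water exchange statistics; systems are finally compared
pairwise on per-replica summaries.  All outputs are TSV plus one
manifest JSON carrying the full configuration (criteria included), the
seed and the package version — no bare numbers.  Identical config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .contacts import (
    ContactCategory,
    classify_frame,
    detect_hbonds,
    detect_salt_bridges,
    detect_water_bridges,
)
from .errors import ConfigError, NoEventError
from .lifetimes import (
    aggregate_replicas,
    autocorrelation,
    correlation_time,
    indicator_series,
    pooled_correlation,
    water_exchange,
)
from .stats import category_fractions, compare_ligands, distance_summary
from .topology import select_atoms
from .traj_io import iter_frames, load_structure, write_run_metadata, write_tsv

__all__ = ["ReplicaResult", "SystemResult", "analyze_system", "run_pipeline"]


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6f}"
    return str(x)


@dataclass
class ReplicaResult:
    replica_id: int
    times_ns: np.ndarray
    categories: list[ContactCategory]
    bundles: list[dict]            # per frame: {"direct": [...], "bridges": [...]}
    direct_distances: list[float]  # min direct-contact distance per direct frame
    contact_rows: list[tuple]


@dataclass
class SystemResult:
    name: str
    replicas: list[ReplicaResult]
    fractions: object
    distances: object | None
    tau: dict          # mode -> {"per_replica": [...], "aggregate": ..., "censored": [...]}
    curves: dict       # mode -> list of CorrelationResult
    exchange: list     # per-replica WaterExchangeSummary


def _residue_atoms(topology, residues: list[dict]) -> np.ndarray:
    idx: list[np.ndarray] = []
    for res in residues:
        sel = select_atoms(topology, chain=res.get("chain"), resid=res.get("resid"))
        if sel.size == 0:
            raise ConfigError(f"residue {res} not found in topology")
        idx.append(sel)
    return np.unique(np.concatenate(idx))


def analyze_system(name: str, spec: dict, cfg: RunConfig) -> SystemResult:
    """Run the per-frame contact analysis for one system."""
    criteria = cfg.criteria
    stride = int(cfg.data["trajectory"]["stride"])
    dt_ns = float(cfg.data["trajectory"]["dt_ns"])
    model = load_structure(
        spec["topology"], ligand_roles=spec.get("ligand_roles")
    )
    top = model.topology
    ligand_idx = select_atoms(top, **spec["ligand"])
    if ligand_idx.size == 0:
        raise ConfigError(f"system {name!r}: ligand selection matched no atoms")
    focal_idx = _residue_atoms(top, [spec["focal"]])
    pocket_idx = _residue_atoms(top, spec["pocket"])

    replicas: list[ReplicaResult] = []
    for r, traj in enumerate(spec["trajectories"]):
        times: list[float] = []
        categories: list[ContactCategory] = []
        bundles: list[dict] = []
        direct_distances: list[float] = []
        rows: list[tuple] = []
        for frame in iter_frames(traj, top, stride=stride, dt_ns=dt_ns):
            hb = detect_hbonds(frame, top, ligand_idx, focal_idx, criteria)
            sb = detect_salt_bridges(frame, top, ligand_idx, focal_idx, criteria)
            bridges = detect_water_bridges(frame, top, ligand_idx, pocket_idx, criteria)
            direct = list(hb) + list(sb)
            cat = classify_frame(direct, bridges)
            times.append(frame.time_ns)
            categories.append(cat)
            bundles.append({"direct": direct, "bridges": bridges})
            if direct:
                direct_distances.append(min(c.distance_A for c in direct))
            for b in hb:
                rows.append(
                    (frame.index, _fmt(frame.time_ns), "hbond", b.donor_atom,
                     b.acceptor_atom, "", _fmt(b.distance_A),
                     _fmt(b.angle_deg) if b.angle_deg is not None else "NA")
                )
            for b in sb:
                rows.append(
                    (frame.index, _fmt(frame.time_ns), "salt_bridge", b.cation_atom,
                     b.anion_atom, "", _fmt(b.distance_A), "NA")
                )
            for b in bridges:
                rows.append(
                    (frame.index, _fmt(frame.time_ns), "water_bridge", b.ligand_atom,
                     b.target_atom, b.water_residue,
                     _fmt(max(b.leg1.distance_A, b.leg2.distance_A)), "NA")
                )
        if not categories:
            raise ConfigError(f"system {name!r}: trajectory {traj} is empty")
        replicas.append(
            ReplicaResult(
                replica_id=r,
                times_ns=np.asarray(times),
                categories=categories,
                bundles=bundles,
                direct_distances=direct_distances,
                contact_rows=rows,
            )
        )

    fractions = category_fractions([(r.replica_id, r.categories) for r in replicas])
    try:
        distances = distance_summary(
            [(r.replica_id, r.direct_distances) for r in replicas],
            interaction_key=(name, "direct"),
        )
    except ValueError:
        distances = None

    lt_cfg = cfg.data["lifetimes"]
    tau: dict = {}
    curves: dict = {}
    for mode in ("direct", "water_mediated"):
        per_tau: list[float] = []
        censored: list[bool] = []
        mode_curves = []
        raw_curves = []
        for rep in replicas:
            try:
                series = indicator_series(
                    rep.bundles, rep.times_ns, mode,
                    replica_id=rep.replica_id, interaction_key=(name, mode),
                )
                corr = autocorrelation(series)
                raw_curves.append(corr)
                corr = correlation_time(
                    corr,
                    method=lt_cfg["tau_method"],
                    plateau_tol=float(lt_cfg["plateau_tol"]),
                    plateau=lt_cfg.get("plateau", "occupancy"),
                    tail_fraction=float(lt_cfg["tail_fraction"]),
                )
            except NoEventError:
                continue
            mode_curves.append(corr)
            per_tau.append(corr.tau_ns)
            censored.append(corr.censored)
        pooled_tau = None
        if raw_curves:
            pooled = correlation_time(
                pooled_correlation(raw_curves),
                method=lt_cfg["tau_method"],
                plateau_tol=float(lt_cfg["plateau_tol"]),
                plateau=lt_cfg.get("plateau", "occupancy"),
                tail_fraction=float(lt_cfg["tail_fraction"]),
            )
            pooled_tau = pooled.tau_ns
        tau[mode] = {
            "per_replica": per_tau,
            "aggregate": aggregate_replicas(per_tau) if per_tau else None,
            "censored": censored,
            "pooled": pooled_tau,
        }
        curves[mode] = mode_curves

    exchange = [
        water_exchange([b["bridges"] for b in rep.bundles],
                       interaction_key=(name, "water_mediated"))
        for rep in replicas
    ]
    return SystemResult(
        name=name, replicas=replicas, fractions=fractions, distances=distances,
        tau=tau, curves=curves, exchange=exchange,
    )


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    cfg.validate_inputs()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    criteria = cfg.criteria
    method_tag = cfg.data["lifetimes"]["tau_method"]
    crit_tag = (
        f"hb<={criteria.hbond_distance_A};sb<={criteria.salt_bridge_A};"
        f"hyd<={criteria.hydrophobic_A}"
    )

    results: dict[str, SystemResult] = {}
    for name in sorted(cfg.systems):
        results[name] = analyze_system(name, cfg.systems[name], cfg)

    outputs: list[str] = []

    for name, res in results.items():
        # per-frame contact table
        rows = []
        for rep in res.replicas:
            for row in rep.contact_rows:
                rows.append((rep.replica_id,) + row + (crit_tag,))
        path = outdir / f"contacts_{name}.tsv"
        write_tsv(
            path,
            ["replica", "frame", "time_ns", "type", "atom_a", "atom_b",
             "water_residue", "distance_A", "angle_deg", "criteria"],
            rows,
        )
        outputs.append(path.name)

        # category series, one column per replica
        n_frames = max(len(r.categories) for r in res.replicas)
        cat_rows = []
        for i in range(n_frames):
            row = [i]
            for rep in res.replicas:
                row.append(
                    rep.categories[i].value if i < len(rep.categories) else ""
                )
            cat_rows.append(tuple(row))
        path = outdir / f"categories_{name}.tsv"
        write_tsv(
            path,
            ["frame"] + [f"replica_{r.replica_id}" for r in res.replicas],
            cat_rows,
        )
        outputs.append(path.name)

        # category fractions (per replica and pooled), percent
        frac_rows = []
        for rid, fd, fw, fn in res.fractions.per_replica:
            frac_rows.append(
                (name, f"replica_{rid}", _fmt(100 * fd), _fmt(100 * fw),
                 _fmt(100 * fn), crit_tag)
            )
        pd_, pw, pn = res.fractions.pooled
        frac_rows.append(
            (name, "pooled", _fmt(100 * pd_), _fmt(100 * pw), _fmt(100 * pn),
             crit_tag)
        )
        path = outdir / f"fractions_{name}.tsv"
        write_tsv(
            path,
            ["system", "unit", "direct_pct", "water_mediated_only_pct",
             "no_polar_contact_pct", "criteria"],
            frac_rows,
        )
        outputs.append(path.name)

        # conditional direct-contact distances
        if res.distances is not None:
            drows = [
                (name, f"replica_{i}", _fmt(m), crit_tag)
                for i, m in enumerate(res.distances.per_replica_means)
            ]
            drows.append((name, "mean", _fmt(res.distances.mean), crit_tag))
            drows.append((name, "sem", _fmt(res.distances.sem), crit_tag))
            path = outdir / f"distances_{name}.tsv"
            write_tsv(
                path, ["system", "unit", "direct_distance_A", "criteria"], drows
            )
            outputs.append(path.name)

        # C(t) curves
        ct_rows = []
        for mode, mode_curves in sorted(res.curves.items()):
            for corr in mode_curves:
                for lag, c in zip(corr.lags_ns, corr.C):
                    ct_rows.append(
                        (name, mode, corr.replica_id, _fmt(lag), _fmt(c))
                    )
        path = outdir / f"ct_{name}.tsv"
        write_tsv(path, ["system", "mode", "replica", "lag_ns", "C"], ct_rows)
        outputs.append(path.name)

        # tau summary
        tau_rows = []
        for mode, info in sorted(res.tau.items()):
            for i, (t, cen) in enumerate(zip(info["per_replica"], info["censored"])):
                tau_rows.append(
                    (name, mode, f"replica_{i}", _fmt(t), str(cen).lower(),
                     method_tag)
                )
            agg = info["aggregate"]
            if agg is not None:
                tau_rows.append(
                    (name, mode, "mean", _fmt(agg.mean), "", method_tag)
                )
                tau_rows.append(
                    (name, mode, "sem", _fmt(agg.sem), "", method_tag)
                )
            if info.get("pooled") is not None:
                tau_rows.append(
                    (name, mode, "pooled", _fmt(info["pooled"]), "", method_tag)
                )
        path = outdir / f"tau_{name}.tsv"
        write_tsv(
            path, ["system", "mode", "unit", "tau_ns", "censored", "method"],
            tau_rows,
        )
        outputs.append(path.name)

        # water exchange
        ex_rows = []
        for i, ex in enumerate(res.exchange):
            ex_rows.append(
                (name, f"replica_{i}", ex.n_bridge_frames,
                 ex.n_identity_switches, ex.distinct_waters,
                 _fmt(ex.switch_fraction))
            )
        path = outdir / f"water_exchange_{name}.tsv"
        write_tsv(
            path,
            ["system", "unit", "n_bridge_frames", "n_identity_switches",
             "distinct_waters", "switch_fraction"],
            ex_rows,
        )
        outputs.append(path.name)

    # pairwise comparisons on per-replica summaries
    comp_rows = []
    pvals = []
    for a, b in itertools.combinations(sorted(results), 2):
        ra, rb = results[a], results[b]
        metrics = {
            "f_direct": (
                [f[1] for f in ra.fractions.per_replica],
                [f[1] for f in rb.fractions.per_replica],
            ),
        }
        for mode in ("direct", "water_mediated"):
            va = ra.tau[mode]["per_replica"]
            vb = rb.tau[mode]["per_replica"]
            if len(va) >= 2 and len(vb) >= 2:
                metrics[f"tau_{mode}"] = (va, vb)
        for metric, (va, vb) in metrics.items():
            try:
                c = compare_ligands(va, vb, label=metric)
            except Exception:
                continue
            comp_rows.append(
                [f"{a}_vs_{b}", metric, _fmt(c.statistic), _fmt(c.p_value),
                 c.test_name, c.n_a, c.n_b]
            )
            pvals.append(c.p_value)
    if comp_rows and cfg.data["stats"]["correction"] == "holm":
        adj = _holm(pvals)
        for row, p in zip(comp_rows, adj):
            row.append(_fmt(p))
        header_extra = ["p_holm"]
    else:
        header_extra = []
    if comp_rows:
        path = outdir / "comparisons.tsv"
        write_tsv(
            path,
            ["pair", "metric", "statistic", "p_value", "test", "n_a", "n_b"]
            + header_extra,
            [tuple(r) for r in comp_rows],
        )
        outputs.append(path.name)

    manifest = {
        "config": cfg.data,
        "config_hash": cfg.config_hash(),
        "criteria": criteria.as_dict(),
        "seed": cfg.seed,
        "outputs": sorted(outputs),
        "aquabridge_version": __version__,
    }
    write_run_metadata(outdir / "manifest.json", manifest)
    return manifest
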