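"""End-to-end two-structure comparison.

Orchestrates the descriptor panel, GNM/ANM dynamics and (optionally)
the iterative-GNM unfolding for a pair of homologous structures from a
single YAML config, and writes plot-ready CSV artifacts plus a run log
recording every parameter and seed.  All residue references in outputs
use author numbering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enm_core, stability_metrics as sm, unfolding as uf
from .structure_io import CaModel, DomainMap, assign_domains, iterative_fit, parse_pdb

__all__ = [
    "RunConfig",
    "StructureReport",
    "ComparisonReport",
    "run_comparison",
    "analyze_structure",
    "validate_against_reference",
]

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    structure_a: str
    structure_b: str
    domains_a: str | None = None
    domains_b: str | None = None
    label_a: str = "A"
    label_b: str = "B"
    chain_a: str | None = None
    chain_b: str | None = None
    out_dir: str = "enmfold_out"
    seed: int = 0
    run_metrics: bool = True
    run_gnm: bool = True
    run_anm: bool = True
    run_unfold: bool = False
    run_fit: bool = True
    replicates: int = 5
    noise_top_k: int = 3
    backbone_factor: float = 10.0
    cutoff_gnm: float = 7.0
    cutoff_anm: float = 13.0
    n_slow_modes: int = 40
    n_fast_modes: int = 10
    weak_step_threshold: int = 500
    use_cache: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("structure_a", "structure_b"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        return cfg


@dataclass
class StructureReport:
    label: str
    n_residues: int
    scalars: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)   # name -> DataFrame
    arrays: dict = field(default_factory=dict)   # name -> ndarray


@dataclass
class ComparisonReport:
    a: StructureReport
    b: StructureReport
    alignment: dict = field(default_factory=dict)
    deltas: dict = field(default_factory=dict)
    config: RunConfig | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for rep in (self.a, self.b):
            for metric, value in sorted(rep.scalars.items()):
                rows.append(
                    {"structure": rep.label, "metric": metric, "value": value}
                )
        for metric, value in sorted(self.alignment.items()):
            rows.append({"structure": "pair", "metric": metric, "value": value})
        for metric, value in sorted(self.deltas.items()):
            rows.append(
                {"structure": "delta_a_minus_b", "metric": metric, "value": value}
            )
        return pd.DataFrame(rows, columns=["structure", "metric", "value"])


def _enm_params(cfg: RunConfig) -> enm_core.ENMParams:
    return enm_core.ENMParams(cutoff_gnm=cfg.cutoff_gnm, cutoff_anm=cfg.cutoff_anm)


def _iter_params(cfg: RunConfig) -> uf.IterativeENMParams:
    return uf.IterativeENMParams(
        enm=_enm_params(cfg),
        backbone_factor=cfg.backbone_factor,
        noise_top_k=cfg.noise_top_k,
        replicates=cfg.replicates,
        seed=cfg.seed,
    )


def _cache_key(pdb_text: str, params: uf.IterativeENMParams) -> str:
    payload = json.dumps(
        {
            "pdb": hashlib.sha256(pdb_text.encode()).hexdigest(),
            "c": params.backbone_factor,
            "k": params.noise_top_k,
            "r": params.replicates,
            "seed": params.seed,
            "cutoff": params.enm.cutoff_gnm,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_unfolding_cached(model, pdb_text, params, cache_dir, log):
    key = _cache_key(pdb_text, params)
    cache_file = Path(cache_dir) / f"unfold_{key}.json" if cache_dir else None
    if cache_file is not None and cache_file.exists():
        log(f"unfolding cache hit: {cache_file.name}")
        raw = json.loads(cache_file.read_text())
        return [
            uf.UnfoldingTrajectory(
                replicate_id=t["replicate_id"],
                seed=t["seed"],
                events=[(s, (i, j), v) for s, i, j, v in t["events"]],
            )
            for t in raw
        ]
    trajectories = uf.run_unfolding(model, params)
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(
            json.dumps(
                [
                    {
                        "replicate_id": t.replicate_id,
                        "seed": t.seed,
                        "events": [(s, p[0], p[1], v) for s, p, v in t.events],
                    }
                    for t in trajectories
                ]
            )
        )
    return trajectories


def analyze_structure(
    model: CaModel,
    domain_map: DomainMap | None,
    cfg: RunConfig,
    label: str,
    pdb_text: str = "",
    cache_dir=None,
    log=lambda msg: None,
) -> StructureReport:
    """Run the enabled analysis stages for one structure."""
    rep = StructureReport(label=label, n_residues=len(model))
    # a CA-only trace parses into single-atom residues; the atom-level
    # descriptors need real side chains / backbones to say anything
    full_atom = any(len(r.atoms) > 1 for r in model.residues)

    if cfg.run_metrics and full_atom:
        log(f"[{label}] metrics: SASA / H-bonds / salt bridges / census")
        sasa_res = sm.sasa(model)
        rep.scalars["sasa_total"] = sasa_res.total
        for klass, (area, frac) in sasa_res.by_class.items():
            rep.scalars[f"sasa_{klass}"] = area
            rep.scalars[f"sasa_{klass}_frac"] = frac
        total, bb, sc, bonds = sm.count_hbonds(model)
        rep.scalars["hbonds_total"] = total
        rep.scalars["hbonds_backbone_backbone"] = bb
        rep.scalars["hbonds_sidechain_involving"] = sc
        n_sb, _bridges = sm.count_salt_bridges(model)
        rep.scalars["salt_bridges"] = n_sb
        gly = sm.classify_glycines(model)
        rep.tables["glycines"] = gly
        rep.scalars["glycine_phi_plus"] = int((gly["cls"] == "phi+").sum())
        rep.scalars["glycine_phi_minus"] = int((gly["cls"] == "phi-").sum())
        buried = sm.buried_hydrophilic_report(model, sasa_res, bonds)
        rep.scalars["buried_hydrophilic"] = buried["n_buried"]
        rep.scalars["buried_hbond_capacity"] = buried["max_capacity"]
        rep.scalars["buried_hbond_actual"] = buried["actual_hbonds"]
        rep.scalars["buried_hbond_ratio"] = buried["ratio"]
    if cfg.run_metrics:
        pro_count = sum(1 for r in model.residues if r.name == "PRO")
        gly_count = sum(1 for r in model.residues if r.name == "GLY")
        rep.scalars["proline_count"] = pro_count
        rep.scalars["proline_fraction"] = pro_count / len(model)
        rep.scalars["glycine_count"] = gly_count
        rep.scalars["glycine_fraction"] = gly_count / len(model)
        if domain_map is not None:
            census, _, _ = sm.residue_census(model, domain_map, "PRO")
            rep.tables["proline_census"] = census
            rep.tables["ncpr"] = sm.ncpr(model, domain_map, cutoff=cfg.cutoff_gnm)

    spec = None
    if cfg.run_gnm:
        log(f"[{label}] GNM decomposition")
        k = enm_core.build_kirchhoff(model, _enm_params(cfg))
        spec, cov = enm_core.pseudo_inverse(k)
        n_slow = min(cfg.n_slow_modes, spec.n_nonzero)
        rep.scalars["gnm_mode_mass_first_%d" % n_slow] = enm_core.mode_mass_fraction(
            spec, n_slow
        )
        cc = enm_core.cross_correlation(spec, range(n_slow))
        rep.arrays["cross_correlation_slow"] = cc
        if domain_map is not None:
            labels = assign_domains(model, domain_map)
            comp = [domain_map.composite_label(l) for l in labels]
            for d in sorted(set(comp)):
                idx = [i for i, c in enumerate(comp) if c == d]
                sub = cc[np.ix_(idx, idx)]
                off = sub[np.triu_indices(len(idx), k=1)]
                if off.size:
                    rep.scalars[f"mean_slow_cc_{d}"] = float(off.mean())
        if cfg.run_fit:
            try:
                gamma, scale, r = enm_core.fit_gamma(model, cov)
                rep.scalars["fitted_gamma"] = gamma
                rep.scalars["bfactor_fit_scale"] = scale
                rep.scalars["bfactor_pearson_r"] = r
                spots = sm.hot_spots(model, spec, scale, n_fast=cfg.n_fast_modes)
                rep.scalars["hot_spots"] = len(spots.hot)
                rep.scalars["warm_spots"] = len(spots.warm)
                rep.tables["spots"] = pd.DataFrame(
                    {
                        "seq_number": model.seq_numbers,
                        "sf_fast": spots.sf,
                        "class": spots.classes,
                    }
                )
            except ValueError as exc:
                log(f"[{label}] gamma fit skipped: {exc}")

    if cfg.run_anm:
        log(f"[{label}] ANM decomposition")
        h = enm_core.build_hessian(model, _enm_params(cfg))
        aspec, _acov = enm_core.pseudo_inverse(h)
        field_1 = enm_core.anm_slow_mode_field(aspec, 1)
        rep.arrays["anm_mode1_field"] = field_1
        rep.scalars["anm_zero_modes"] = aspec.zero_mode_count

    if cfg.run_unfold:
        log(f"[{label}] iterative-GNM unfolding ({cfg.replicates} replicates)")
        params = _iter_params(cfg)
        topo0 = uf.native_topology(model, params)
        rep.scalars["native_noncovalent_contacts"] = topo0.native_noncovalent_count
        trajectories = _run_unfolding_cached(
            model, pdb_text, params, cache_dir, log
        )
        rep.arrays["trajectories"] = trajectories
        rep.arrays["_seq_numbers"] = model.seq_numbers
        if domain_map is not None:
            curves = uf.unfolding_curves(trajectories, topo0, model, domain_map)
            frame = {"step": curves.steps}
            for d, vals in curves.intra.items():
                frame[f"intra_{d}"] = vals
            for d, vals in curves.inter.items():
                frame[f"inter_{d}"] = vals
            rep.tables["unfolding_curves"] = pd.DataFrame(frame)
        report = uf.weak_regions(
            trajectories,
            topo0,
            model.coords,
            step_threshold=min(
                cfg.weak_step_threshold, topo0.native_noncovalent_count
            ),
            model=model,
            domain_map=domain_map,
        )
        seq = model.seq_numbers
        rows = []
        for region in report.regions:
            for i, j in region.pairs:
                rows.append(
                    {
                        "cluster": region.cluster_id,
                        "res_i": int(seq[i]),
                        "res_j": int(seq[j]),
                        "mean_break_step": region.mean_break_step,
                        "domains": "+".join(region.domains),
                    }
                )
        rep.tables["weak_regions"] = pd.DataFrame(
            rows, columns=["cluster", "res_i", "res_j", "mean_break_step", "domains"]
        )
        rep.scalars["weak_region_clusters"] = len(report.regions)
    return rep


def run_comparison(cfg: RunConfig) -> ComparisonReport:
    """Execute the full comparison and write artifacts to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    log("run configuration:")
    for key, val in sorted(vars(cfg).items()):
        log(f"  {key} = {val!r}")

    mode = "full_atom"
    text_a = Path(cfg.structure_a).read_text()
    text_b = Path(cfg.structure_b).read_text()
    model_a = parse_pdb(text_a, mode=mode, chain=cfg.chain_a, source_id=cfg.label_a)
    model_b = parse_pdb(text_b, mode=mode, chain=cfg.chain_b, source_id=cfg.label_b)
    dm_a = (
        DomainMap.from_config(Path(cfg.domains_a).read_text())
        if cfg.domains_a
        else None
    )
    dm_b = (
        DomainMap.from_config(Path(cfg.domains_b).read_text())
        if cfg.domains_b
        else None
    )
    cache_dir = out / "cache" if cfg.use_cache else None
    rep_a = analyze_structure(
        model_a, dm_a, cfg, cfg.label_a, text_a, cache_dir, log
    )
    rep_b = analyze_structure(
        model_b, dm_b, cfg, cfg.label_b, text_b, cache_dir, log
    )

    log("structure-based superposition")
    fit = iterative_fit(model_a, model_b)
    alignment = {
        "matched_positions": len(fit.pairs),
        "rmsd": fit.rmsd,
        "identity_fraction": fit.identity_fraction,
    }

    deltas = {
        k: rep_a.scalars[k] - rep_b.scalars[k]
        for k in rep_a.scalars
        if k in rep_b.scalars
        and isinstance(rep_a.scalars[k], (int, float))
        and isinstance(rep_b.scalars[k], (int, float))
    }
    report = ComparisonReport(
        a=rep_a, b=rep_b, alignment=alignment, deltas=deltas, config=cfg
    )
    _write_artifacts(report, out, log_lines)
    return report


def _csv_header(cfg: RunConfig | None) -> str:
    seed = cfg.seed if cfg is not None else 0
    return f"# enmfold report; seed={seed}\n"


def _write_artifacts(report: ComparisonReport, out: Path, log_lines):
    header = _csv_header(report.config)
    summary = report.summary_frame()
    with open(out / "summary.csv", "w") as fh:
        fh.write(header)
        summary.to_csv(fh, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    for rep in (report.a, report.b):
        for name, table in rep.tables.items():
            with open(out / f"{rep.label}_{name}.csv", "w") as fh:
                fh.write(header)
                table.to_csv(
                    fh, index=False, float_format=FLOAT_FMT, lineterminator="\n"
                )
        for name, arr in rep.arrays.items():
            if name.startswith("_"):
                continue
            if name == "trajectories":
                for t in arr:
                    frame = pd.DataFrame(
                        [
                            {
                                "step": s,
                                "res_i": int(report_seq(rep, i)),
                                "res_j": int(report_seq(rep, j)),
                                "fluctuation": v,
                                "lnnc": s,
                            }
                            for s, (i, j), v in t.events
                        ]
                    )
                    path = out / f"{rep.label}_trajectory_{t.replicate_id}.csv"
                    with open(path, "w") as fh:
                        fh.write(f"# enmfold trajectory; seed={t.seed}\n")
                        frame.to_csv(
                            fh, index=False, float_format=FLOAT_FMT,
                            lineterminator="\n",
                        )
                continue
            np.savetxt(
                out / f"{rep.label}_{name}.csv",
                np.asarray(arr),
                delimiter=",",
                fmt=FLOAT_FMT,
                header=f"enmfold report; seed={report.config.seed if report.config else 0}",
            )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")


def report_seq(rep: StructureReport, index: int) -> int:
    """Author seq number for a 0-based index (trajectory CSV output)."""
    seq = rep.arrays.get("_seq_numbers")
    if seq is None:
        return index + 1
    return int(seq[index])


def validate_against_reference(report: ComparisonReport, reference_csv) -> list:
    """Compare a report's summary against a reference table.

    The reference CSV needs columns structure, metric, value and
    optionally tol_abs / tol_rel (defaults: exact for integers, 1e-9
    relative otherwise).  Returns a list of dicts with pass/fail per
    reference row; raises on schema mismatch (unknown metric).
    """
    ref = pd.read_csv(reference_csv, comment="#")
    required = {"structure", "metric", "value"}
    if not required.issubset(ref.columns):
        raise ValueError(f"reference table must have columns {sorted(required)}")
    summary = report.summary_frame()
    results = []
    for _, row in ref.iterrows():
        match = summary[
            (summary["structure"] == row["structure"])
            & (summary["metric"] == row["metric"])
        ]
        if match.empty:
            raise ValueError(
                f"metric {row['metric']!r} for {row['structure']!r} not in report"
            )
        got = float(match["value"].iloc[0])
        want = float(row["value"])
        tol_abs = float(row.get("tol_abs", 0.0) or 0.0)
        tol_rel = float(row.get("tol_rel", 0.0) or 0.0)
        if tol_abs == 0.0 and tol_rel == 0.0:
            tol_rel = 1e-9
        ok = abs(got - want) <= max(tol_abs, tol_rel * abs(want))
        results.append(
            {
                "structure": row["structure"],
                "metric": row["metric"],
                "reference": want,
                "computed": got,
                "pass": bool(ok),
            }
        )
    return results
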