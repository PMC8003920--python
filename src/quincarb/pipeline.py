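"""End-to-end orchestration of the three analysis stages.

Stages: kinetics (activity time courses -> k_i / k_max / K_a per compound
and enzyme), qsar (energy fingerprints + response -> NIPALS-PCA polynomial
model with LOO selection) and bbb (structures/descriptors -> CNS rule
verdicts).  ``run_all`` chains them, optionally handing the kinetics-stage
fitted K_a values to the qsar stage as the response, and writes a MANIFEST
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import chemometrics, cns, kinetics, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "validate_config",
    "load_config",
    "run_kinetics",
    "run_qsar",
    "run_bbb",
    "run_all",
]


class ConfigError(ValueError):
    """Configuration file failed validation; message lists every problem."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


_SCHEMA: Dict[str, Dict[str, Any]] = {
    "stages": {"default": ["kinetics", "qsar", "bbb"], "type": list},
    "out_dir": {"default": "results", "type": str},
    "seed": {"default": 0, "type": int},
    "kinetics": {
        "activity_csv": {"default": None, "type": str},
        "alpha": {"default": 0.05, "type": float},
        "ka_guard": {"default": 5.0, "type": float},
        "weighted": {"default": False, "type": bool},
        "through_origin": {"default": True, "type": bool},
    },
    "qsar": {
        "energies_csv": {"default": None, "type": str},
        "response_csv": {"default": None, "type": str},
        "response_col": {"default": "Ka_M", "type": str},
        "transform": {"default": "log10", "type": str},
        "n_pcs": {"default": 2, "type": int},
        "degrees": {"default": [1, 2, 3, 4, 5], "type": list},
        "use_kinetics_ka": {"default": False, "type": bool},
    },
    "bbb": {
        "structures_smi": {"default": None, "type": str},
        "descriptors_csv": {"default": None, "type": str},
        "use_paper_compounds": {"default": False, "type": bool},
        "hbd_convention": {"default": "donor_hydrogens", "type": str},
    },
}


@dataclass
class RunConfig:
    stages: List[str]
    out_dir: str
    seed: int
    kinetics: Dict[str, Any]
    qsar: Dict[str, Any]
    bbb: Dict[str, Any]

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _coerce(value, expected, path, errors):
    if value is None or isinstance(value, expected):
        return value
    if expected is float and isinstance(value, int) and not isinstance(value, bool):
        return float(value)
    errors.append(f"{path}: expected {expected.__name__}, got {type(value).__name__}")
    return value


def validate_config(raw: Optional[Dict[str, Any]]) -> RunConfig:
    """Validate and default a raw config mapping.

    Unknown keys are rejected; every violation is collected and reported in
    one :class:`ConfigError` with its key path.
    """
    raw = dict(raw or {})
    errors: List[str] = []
    resolved: Dict[str, Any] = {}
    for key, spec in _SCHEMA.items():
        if "type" in spec and not isinstance(spec.get("type"), dict):
            value = raw.pop(key, spec["default"])
            resolved[key] = _coerce(value, spec["type"], key, errors)
        else:  # nested stage section
            section = raw.pop(key, {}) or {}
            if not isinstance(section, dict):
                errors.append(f"{key}: expected a mapping")
                section = {}
            out: Dict[str, Any] = {}
            for skey, sspec in spec.items():
                value = section.pop(skey, sspec["default"])
                out[skey] = _coerce(value, sspec["type"], f"{key}.{skey}", errors)
            for unknown in section:
                errors.append(f"{key}.{unknown}: unknown key")
            resolved[key] = out
    for unknown in raw:
        errors.append(f"{unknown}: unknown key")
    known_stages = {"kinetics", "qsar", "bbb"}
    for s in resolved.get("stages") or []:
        if s not in known_stages:
            errors.append(f"stages: unknown stage {s!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(**resolved)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON config file, validate, and check referenced inputs."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = validate_config(raw)
    missing = []
    for section, key in (
        ("kinetics", "activity_csv"),
        ("qsar", "energies_csv"),
        ("qsar", "response_csv"),
        ("bbb", "structures_smi"),
        ("bbb", "descriptors_csv"),
    ):
        p = getattr(cfg, section).get(key)
        if p is not None and not Path(p).exists():
            missing.append(f"{section}.{key}: file not found: {p}")
    if missing:
        raise ConfigError("; ".join(missing))
    return cfg


# ---------------------------------------------------------------------------
# stage runners


def read_activity_csv(path: str | Path) -> List[kinetics.ActivitySeries]:
    """Parse the activity table (concentrations in uM, times in minutes).

    Columns: compound_id, enzyme, qc_conc_uM, time_min, velocity, is_control.
    Control rows (is_control=1 or qc_conc_uM=0) define v0 per compound and
    enzyme as the mean control velocity.
    """
    df = pd.read_csv(path)
    required = {"compound_id", "enzyme", "qc_conc_uM", "time_min", "velocity"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity CSV must have columns {sorted(required)}")
    if "is_control" not in df.columns:
        df["is_control"] = (df["qc_conc_uM"] == 0).astype(int)
    out: List[kinetics.ActivitySeries] = []
    for (cid, enzyme), grp in df.groupby(["compound_id", "enzyme"], sort=False):
        controls = grp[grp["is_control"] == 1]
        if controls.empty:
            raise ValueError(f"no control rows for {cid}/{enzyme}")
        v0 = float(controls["velocity"].mean())
        for conc, sub in grp[grp["is_control"] == 0].groupby("qc_conc_uM", sort=True):
            out.append(
                kinetics.ActivitySeries(
                    compound_id=str(cid), enzyme=str(enzyme),
                    qc_conc=float(conc) * 1e-6,
                    times=sub["time_min"].to_numpy(float),
                    velocities=sub["velocity"].to_numpy(float),
                    v0=v0,
                )
            )
    return out


def series_to_frame(series: List[kinetics.ActivitySeries]) -> pd.DataFrame:
    """Serialise ActivitySeries back to the activity CSV schema (uM, min)."""
    rows = []
    seen_controls = set()
    for s in series:
        key = (s.compound_id, s.enzyme)
        if s.qc_conc == 0 or key not in seen_controls:
            # one synthetic control row pinning v0
            rows.append(dict(compound_id=s.compound_id, enzyme=s.enzyme,
                             qc_conc_uM=0.0, time_min=0.0, velocity=s.v0,
                             is_control=1))
            seen_controls.add(key)
        if s.qc_conc > 0:
            for t, v in zip(s.times, s.velocities):
                rows.append(dict(compound_id=s.compound_id, enzyme=s.enzyme,
                                 qc_conc_uM=s.qc_conc * 1e6, time_min=t,
                                 velocity=v, is_control=0))
    return pd.DataFrame(rows)


def run_kinetics(
    series: List[kinetics.ActivitySeries],
    alpha: float = 0.05,
    ka_guard: float = 5.0,
    weighted: bool = False,
    through_origin: bool = True,
) -> pd.DataFrame:
    """Fit every compound/enzyme group: k_obs per concentration, then the
    concentration dependence.  Returns the kinetics results table."""
    groups: Dict[tuple, List[kinetics.ActivitySeries]] = {}
    for s in series:
        if s.qc_conc > 0:
            groups.setdefault((s.compound_id, s.enzyme), []).append(s)
    rows = []
    for (cid, enzyme), members in groups.items():
        pairs = []
        for s in sorted(members, key=lambda s: s.qc_conc):
            est = kinetics.fit_kobs(s, through_origin=through_origin)
            pairs.append((s.qc_conc, est))
        fit = kinetics.fit_concentration_dependence(
            pairs, alpha=alpha, ka_guard=ka_guard, weighted=weighted
        )
        rows.append(dict(
            compound_id=cid, enzyme=enzyme, mode=fit.mode,
            k_i_1e3_per_M_min=fit.k_i / 1e3,
            k_i_ci_low=fit.k_i_ci[0] / 1e3, k_i_ci_high=fit.k_i_ci[1] / 1e3,
            k_max_per_min=fit.k_max, K_a_uM=None if fit.K_a is None else fit.K_a * 1e6,
            F_p_value=fit.p_value, n_concentrations=fit.n_concentrations,
        ))
    return pd.DataFrame(rows)


def run_qsar(
    energies: pd.DataFrame,
    response: pd.Series,
    n_pcs: int = 2,
    degrees: List[int] = (1, 2, 3, 4, 5),
    transform: str = "log10",
) -> Dict[str, Any]:
    """PCA + polynomial model selection; returns a JSON-ready summary."""
    if transform == "log10":
        y = np.log10(response.to_numpy(float))
    elif transform == "identity":
        y = response.to_numpy(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    Xc, means = chemometrics.mean_center(energies.to_numpy(float))
    pca = chemometrics.nipals_pca(Xc, n_components=n_pcs)
    model, report = chemometrics.select_model(pca.scores, y, degrees=degrees)
    return {
        "n_pcs": n_pcs,
        "transform": transform,
        "explained_variance": pca.explained.tolist(),
        "cumulative_explained": pca.cumulative_explained.tolist(),
        "selected_degree": model.degree,
        "terms": [list(t) for t in model.terms],
        "coefficients": model.coefficients.tolist(),
        "r2": model.r_squared,
        "se_regression": model.se_regression,
        "cv_mse": report.cv_mse,
        "avg_r2_loo": report.avg_r2_loo,
        "q2": report.q2,
        "scores": pd.DataFrame(
            pca.scores, index=energies.index,
            columns=[f"PC{i + 1}" for i in range(n_pcs)],
        ),
        "loadings": pd.DataFrame(
            pca.loadings, index=energies.columns,
            columns=[f"PC{i + 1}" for i in range(n_pcs)],
        ),
    }


def run_bbb(
    structures=None,
    table: Optional[pd.DataFrame] = None,
    hbd_convention: str = "donor_hydrogens",
) -> Dict[str, Any]:
    descriptors = cns.acquire_descriptors(
        structures=structures, table=table, hbd_convention=hbd_convention
    )
    reports = [cns.cns_rule_check(d) for d in descriptors]
    radar = cns.export_radar(descriptors)
    return {
        "descriptors": descriptors,
        "reports": reports,
        "radar": radar,
        "summary": [
            {
                "compound_id": r.compound_id,
                "verdict": "pass" if r.verdict else "fail",
                "statuses": r.statuses,
                "violated": r.violated,
            }
            for r in reports
        ],
    }


# ---------------------------------------------------------------------------
# orchestration


def _params_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_all(cfg: RunConfig) -> Dict[str, Any]:
    """Execute the configured stages in order, writing one summary bundle.

    A stage failure aborts downstream stages; partial outputs are retained
    and the MANIFEST records the completion state of every stage.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "package_version": __version__,
        "seed": cfg.seed,
        "params_hash": _params_hash(cfg),
        "config": cfg.to_dict(),
        "stages": {},
    }
    summary: Dict[str, Any] = {}
    failed = False
    kinetics_table: Optional[pd.DataFrame] = None

    for stage in cfg.stages:
        if failed:
            manifest["stages"][stage] = "skipped"
            continue
        try:
            if stage == "kinetics":
                src = cfg.kinetics["activity_csv"]
                if src is None:
                    series, truth = synthetic.generate_panel(seed=cfg.seed)
                    logger.info("kinetics: no input file, simulated a panel")
                else:
                    series = read_activity_csv(src)
                kinetics_table = run_kinetics(
                    series,
                    alpha=cfg.kinetics["alpha"], ka_guard=cfg.kinetics["ka_guard"],
                    weighted=cfg.kinetics["weighted"],
                    through_origin=cfg.kinetics["through_origin"],
                )
                kinetics_table.to_csv(out_dir / "kinetics_results.csv", index=False)
                (out_dir / "kinetics_results.json").write_text(
                    kinetics_table.to_json(orient="records", indent=2)
                )
                summary["kinetics"] = kinetics_table.to_dict(orient="records")
            elif stage == "qsar":
                qcfg = cfg.qsar
                transform = qcfg["transform"]
                if qcfg["energies_csv"] is not None:
                    energies = pd.read_csv(qcfg["energies_csv"], index_col=0)
                else:
                    energies, resp, _ = synthetic.generate_fingerprints(
                        truth=synthetic.FingerprintTruth(seed=cfg.seed)
                    )
                    if qcfg["response_csv"] is None and not qcfg["use_kinetics_ka"]:
                        # the planted synthetic response is already on a
                        # modelling scale (and signed); a log would be invalid
                        transform = "identity"
                        logger.info("qsar: synthetic response, identity transform")
                if qcfg["use_kinetics_ka"]:
                    if kinetics_table is None:
                        raise StageError("use_kinetics_ka requires the kinetics stage")
                    sat = kinetics_table[kinetics_table["mode"] == "saturation"]
                    dropped = set(kinetics_table["compound_id"]) - set(sat["compound_id"])
                    if dropped:
                        logger.info(
                            "qsar: excluding linear-mode compounds without an "
                            "identifiable K_a: %s", sorted(dropped),
                        )
                    resp = pd.Series(
                        (sat["K_a_uM"] * 1e-6).to_numpy(),
                        index=sat["compound_id"], name="Ka_M",
                    )
                    energies = energies.loc[resp.index.intersection(energies.index)]
                    resp = resp.loc[energies.index]
                elif qcfg["response_csv"] is not None:
                    rdf = pd.read_csv(qcfg["response_csv"]).set_index("compound_id")
                    resp = rdf[qcfg["response_col"]]
                    resp = resp.loc[energies.index]
                result = run_qsar(
                    energies, resp, n_pcs=qcfg["n_pcs"],
                    degrees=list(qcfg["degrees"]), transform=transform,
                )
                result.pop("scores").to_csv(out_dir / "scores.csv")
                result.pop("loadings").to_csv(out_dir / "loadings.csv")
                (out_dir / "qsar_model.json").write_text(json.dumps(result, indent=2))
                summary["qsar"] = result
            elif stage == "bbb":
                bcfg = cfg.bbb
                structures = None
                table = None
                if bcfg["use_paper_compounds"] or (
                    bcfg["structures_smi"] is None and bcfg["descriptors_csv"] is None
                ):
                    fixture = synthetic.paper_compounds()
                    structures = list(zip(fixture["id"].astype(str), fixture["smiles"]))
                elif bcfg["structures_smi"] is not None:
                    lines = Path(bcfg["structures_smi"]).read_text().splitlines()
                    structures = []
                    for line in lines:
                        if line.strip():
                            smi, _, cid = line.strip().partition(" ")
                            structures.append((cid.strip() or smi, smi))
                if bcfg["descriptors_csv"] is not None:
                    table = pd.read_csv(bcfg["descriptors_csv"])
                result = run_bbb(structures=structures, table=table,
                                 hbd_convention=bcfg["hbd_convention"])
                (out_dir / "bbb_report.json").write_text(
                    json.dumps(result["summary"], indent=2)
                )
                result["radar"].to_csv(out_dir / "radar.csv")
                summary["bbb"] = result["summary"]
            manifest["stages"][stage] = "completed"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = f"failed: {exc}"
            failed = True
    (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    if failed:
        raise StageError("pipeline aborted; see MANIFEST.json")
    return summary
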