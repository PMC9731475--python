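"""Pipeline assembly: run the algebraic, Bayesian-network and clustering
techniques in parallel on the same species-day tables and combine their
signals.

The three techniques are complementary views of the same daily risk: the
combined flag for a species-day is *elevated* iff any one of them signals a
heightened likelihood — a deliberately conservative disjunction, since the
cost of a missed warning (a strike) far exceeds the cost of a false alert.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .algebraic import ThresholdRule, classify_day, fit_mix, fit_threshold_rule
from .bayesnet import (
    BayesNet,
    LikelihoodLabelSpec,
    NetworkStructure,
    build_network,
    crossvalidate,
    derive_likelihood_label,
    discretise_cases,
    infer,
    learn_cpts,
)
from .data import Dataset, build_species_day_table, read_dataset
from .daytypes import (
    dunn,
    hopkins,
    kmeans,
    round_half_up,
    silhouette,
    standardise,
    strike_association,
)
from .seasonal import SeasonalitySpec, add_seasonal_features

__all__ = [
    "RunConfig",
    "LikelihoodReport",
    "default_structure",
    "feature_matrix",
    "bn_node_frame",
    "run_pipeline",
    "render_tables",
]

_CONFIG_FILES = {
    "Cattle Egret": "cattle_egret.yaml",
    "Nankeen Kestrel": "nankeen_kestrel.yaml",
    "Straw-necked Ibis": "straw_necked_ibis.yaml",
}


def default_structure(species: str) -> NetworkStructure:
    """The shipped network structure for one of the three default species."""
    fname = _CONFIG_FILES.get(species)
    if fname is None:
        raise KeyError(f"no default structure for species {species!r}")
    ref = importlib.resources.files("strikerisk.configs") / fname
    with importlib.resources.as_file(ref) as path:
        return NetworkStructure.from_yaml(path)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one data source."""

    seed: int
    dataset_paths: dict | None = None
    generator: object | None = None  # a synthetic.GeneratorConfig
    species: list[str] | None = None
    seasonality_mode: str = "angular"
    marker_dates: dict[str, dt.date] = field(default_factory=dict)
    kernel_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    structure_files: dict[str, str] = field(default_factory=dict)
    cluster_k: int = 2
    bootstrap_B: int = 10_000
    cv_folds: int = 2
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.dataset_paths is None) == (self.generator is None):
            raise ValueError("exactly one of dataset_paths / generator must be given")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        markers = {
            sp: dt.date.fromisoformat(v) for sp, v in (doc.get("marker_dates") or {}).items()
        }
        kcounts = {
            sp: tuple(v) for sp, v in (doc.get("kernel_counts") or {}).items()
        }
        gen = None
        if doc.get("generator"):
            from .synthetic import default_config

            g = doc["generator"]
            gen = default_config(
                seed=g.get("seed", seed if seed is not None else 0),
                n_days=g.get("n_days", 761),
            )
        return cls(
            seed=seed if seed is not None else int(doc.get("seed", 0)),
            dataset_paths=doc.get("dataset_paths"),
            generator=gen,
            species=doc.get("species"),
            seasonality_mode=doc.get("seasonality_mode", "angular"),
            marker_dates=markers,
            kernel_counts=kcounts,
            structure_files=doc.get("structure_files") or {},
            cluster_k=int(doc.get("cluster_k", 2)),
            bootstrap_B=int(doc.get("bootstrap_B", 10_000)),
            cv_folds=int(doc.get("cv_folds", 2)),
            out_dir=doc.get("out_dir"),
        )


@dataclass
class LikelihoodReport:
    """Per species-day signals from each technique and the combined flag."""

    rows: pd.DataFrame
    rules: dict[str, ThresholdRule]
    bn_cv: dict[str, dict]
    cluster_validation: dict[str, dict]
    associations: dict[str, pd.DataFrame]
    stage_status: dict[str, dict[str, str]]


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The day-type feature matrix.  Strike flags are never included."""
    obs_cols = [c for c in table.columns if c.startswith("observed_")]
    har_cols = [c for c in table.columns if c.startswith("harassed_")]
    out = pd.DataFrame(
        {
            "abundance": table["abundance"],
            "total_observed": table[obs_cols].sum(axis=1),
            "total_harassed": table[har_cols].sum(axis=1),
            "seasonality": table["seasonality"],
            "rain_mm": table["rain_mm"],
            "temp_c": table["temp_c"],
            "aircraft_movements": table["aircraft_movements"],
        }
    )
    assert "strike" not in out.columns
    return out.fillna(out.mean(numeric_only=True))


def bn_node_frame(table: pd.DataFrame, zone_map, net: BayesNet) -> pd.DataFrame:
    """Raw per-day values for every node the network declares.

    Node vocabulary: Season (seasonality score), Temperature, Rain,
    Seasonal/Hunting Behaviour (expected abundance — the behaviour-driven
    seasonal mean), Observed Count, Zone Population (birds in the two
    closest proximity bands), All Population (observed + harassed),
    Aircraft Movement, Likelihood (proximity-weighted location-risk score).
    """
    obs_cols = [c for c in table.columns if c.startswith("observed_")]
    har_cols = [c for c in table.columns if c.startswith("harassed_")]
    near = [
        f"observed_{z}" for z in zone_map.zone_ids() if zone_map.get(z).proximity <= 2
    ]
    raw_label = table.apply(lambda r: derive_likelihood_label(r, zone_map), axis=1)
    values = {
        "Season": table["seasonality"],
        "Temperature": table["temp_c"].fillna(table["temp_c"].mean()),
        "Rain": table["rain_mm"].fillna(0.0),
        "Seasonal Behaviour": table.get("expected_abundance", table["abundance"]),
        "Hunting Behaviour": table.get("expected_abundance", table["abundance"]),
        "Observed Count": table[obs_cols].sum(axis=1),
        "Zone Population": table[near].sum(axis=1) if near else table[obs_cols].sum(axis=1),
        "All Population": table[obs_cols].sum(axis=1) + table[har_cols].sum(axis=1),
        "Aircraft Movement": table["aircraft_movements"].fillna(
            table["aircraft_movements"].mean()
        ),
        "Likelihood": raw_label,
    }
    return pd.DataFrame({n: values[n] for n in net.order})


def _load_dataset(cfg: RunConfig) -> Dataset:
    if cfg.dataset_paths is not None:
        return read_dataset(cfg.dataset_paths)
    from .synthetic import generate_dataset

    ds, _ = generate_dataset(cfg.generator)
    return ds


def run_pipeline(cfg: RunConfig) -> LikelihoodReport:
    """Execute the three techniques per species and assemble the report.

    A failing stage is recorded in ``stage_status`` and its signal treated
    as low for the affected species, so one bad stage never hides the
    others' warnings.
    """
    ds = _load_dataset(cfg)
    species = cfg.species or ds.species_list
    all_rows: list[pd.DataFrame] = []
    rules: dict[str, ThresholdRule] = {}
    bn_cv: dict[str, dict] = {}
    cluster_val: dict[str, dict] = {}
    associations: dict[str, pd.DataFrame] = {}
    status: dict[str, dict[str, str]] = {}

    for sp in species:
        status[sp] = {"algebraic": "ok", "bayes": "ok", "cluster": "ok"}
        marker = cfg.marker_dates.get(sp, ds.date_range[0])
        spec = SeasonalitySpec(marker, cfg.seasonality_mode)
        table = add_seasonal_features(build_species_day_table(ds, sp), ds.zone_map, spec)

        rows = pd.DataFrame(
            {
                "date": table["date"],
                "species": sp,
                "strike": table["strike"],
            }
        )

        # --- A: algebraic -------------------------------------------------
        alg_flag = np.zeros(len(table), dtype=bool)
        try:
            m, n = cfg.kernel_counts.get(sp, (1, 0))
            mix, _ = fit_mix(
                np.column_stack([table["seasonality"], table["abundance"]]),
                m=m,
                n=n,
                seed=derive_seed(cfg.seed, sp, "fit"),
                seasonality=spec,
            )
            table["expected_abundance"] = np.asarray(mix(table["seasonality"].to_numpy()))
            rule = fit_threshold_rule(table, seed=derive_seed(cfg.seed, sp, "rule"))
            rules[sp] = rule
            alg_flag = np.array(
                [classify_day(rule, r) == "elevated" for _, r in table.iterrows()]
            )
        except Exception as exc:  # recorded, not fatal
            status[sp]["algebraic"] = f"failed: {exc}"
            table["expected_abundance"] = table["abundance"]
        rows["algebraic"] = np.where(alg_flag, "elevated", "low")

        # --- B: Bayesian network -----------------------------------------
        bn_flag = np.zeros(len(table), dtype=bool)
        p_high = np.full(len(table), np.nan)
        try:
            if sp in cfg.structure_files:
                structure = NetworkStructure.from_yaml(cfg.structure_files[sp])
            else:
                structure = default_structure(sp)
            net = build_network(structure)
            raw = bn_node_frame(table, ds.zone_map, net)
            cases = discretise_cases(net, raw)
            bn_cv[sp] = {
                k: v
                for k, v in crossvalidate(
                    net, cases, K=cfg.cv_folds, seed=derive_seed(cfg.seed, sp, "cv")
                ).items()
                if k in ("fold_accuracy", "mean_accuracy")
            }
            cpts = learn_cpts(net, cases)
            others = [nname for nname in net.order if nname != "Likelihood"]
            hi = net.card("Likelihood") - 1
            for i in range(len(cases)):
                ev = {nname: int(cases.iloc[i][nname]) for nname in others}
                post = infer(net, cpts, ev, "Likelihood")
                p_high[i] = post[hi]
                bn_flag[i] = int(np.argmax(post)) == hi
        except Exception as exc:
            status[sp]["bayes"] = f"failed: {exc}"
        rows["bn_p_high"] = p_high
        rows["bayes"] = np.where(bn_flag, "elevated", "low")

        # --- C: day typing ------------------------------------------------
        cl_flag = np.zeros(len(table), dtype=bool)
        rows["cluster"] = 0
        try:
            feats = feature_matrix(table)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Z, _, _, _ = standardise(feats)
            model = kmeans(Z, cfg.cluster_k, seed=derive_seed(cfg.seed, sp, "kmeans"))
            sil_vals, sil_avg = silhouette(Z, model.assignments)
            cluster_val[sp] = {
                "silhouette_avg": sil_avg,
                "dunn": dunn(Z, model.assignments),
                "hopkins": hopkins(Z, seed=derive_seed(cfg.seed, sp, "hopkins")),
                "sizes": np.bincount(model.assignments)[1:].tolist(),
            }
            assoc = strike_association(
                model.assignments,
                table["strike"].to_numpy(),
                B=cfg.bootstrap_B,
                seed=derive_seed(cfg.seed, sp, "bootstrap"),
            )
            associations[sp] = assoc.table
            overall_p = assoc.table.iloc[0]["p"]
            risky = {
                row["cluster"]
                for _, row in assoc.table.iloc[1:].iterrows()
                if row["overlap"] == "N" and row["p"] > overall_p
            }
            rows["cluster"] = model.assignments
            cl_flag = np.array([str(a) in risky for a in model.assignments])
        except Exception as exc:
            status[sp]["cluster"] = f"failed: {exc}"
        rows["cluster_elevated"] = cl_flag

        rows["combined"] = np.where(
            alg_flag | bn_flag | cl_flag, "elevated", "low"
        )
        all_rows.append(rows)

    report = LikelihoodReport(
        rows=pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame(),
        rules=rules,
        bn_cv=bn_cv,
        cluster_validation=cluster_val,
        associations=associations,
        stage_status=status,
    )
    if cfg.out_dir:
        render_tables(report, cfg.out_dir)
    return report


def render_tables(report: LikelihoodReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report's artefact files with deterministic formatting.

    Probabilities at 3 decimals, validity indices at 2; columns in fixed
    order so re-runs with the same seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    daily = report.rows.copy()
    if len(daily):
        daily["bn_p_high"] = [
            "" if np.isnan(v) else f"{round_half_up(v, 3):.3f}" for v in daily["bn_p_high"]
        ]
    paths["daily"] = out / "daily_likelihood.csv"
    daily.to_csv(paths["daily"], index=False)

    assoc_frames = []
    for sp, tbl in report.associations.items():
        t = tbl.copy()
        t.insert(0, "species", sp)
        assoc_frames.append(t)
    assoc = (
        pd.concat(assoc_frames, ignore_index=True)
        if assoc_frames
        else pd.DataFrame(
            columns=["species", "cluster", "days", "strikes", "p", "ci_low", "ci_high", "overlap"]
        )
    )
    for col in ("p", "ci_low", "ci_high"):
        if len(assoc):
            assoc[col] = [f"{round_half_up(v, 3):.3f}" for v in assoc[col]]
    paths["association"] = out / "cluster_association.csv"
    assoc.to_csv(paths["association"], index=False)

    validation = {
        sp: {
            "silhouette_avg": round_half_up(v["silhouette_avg"], 2),
            "dunn": round_half_up(v["dunn"], 2),
            "hopkins": round_half_up(v["hopkins"], 2),
            "sizes": v["sizes"],
        }
        for sp, v in report.cluster_validation.items()
    }
    import json

    paths["validation"] = out / "cluster_validation.json"
    paths["validation"].write_text(json.dumps(validation, indent=2, sort_keys=True))

    rules_doc = {}
    for sp, rule in report.rules.items():
        rules_doc[sp] = {
            "attribute": rule.attribute,
            "threshold": rule.threshold,
            "direction": rule.direction,
            "accuracy": rule.accuracy,
            "f_score": rule.f_score,
        }
    paths["rules"] = out / "threshold_rules.json"
    paths["rules"].write_text(json.dumps(rules_doc, indent=2, sort_keys=True))

    paths["bn_cv"] = out / "bn_crossvalidation.json"
    paths["bn_cv"].write_text(
        json.dumps(
            {
                sp: {
                    "fold_accuracy": [round_half_up(a, 3) for a in v["fold_accuracy"]],
                    "mean_accuracy": round_half_up(v["mean_accuracy"], 3),
                }
                for sp, v in report.bn_cv.items()
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths
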