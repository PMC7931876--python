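"""End-to-end orchestration: simulate/load -> curate -> select -> score ->
network -> communities, with a manifest and byte-reproducible artifacts.

A single master seed deterministically derives one sub-seed per stage (the
stage name is hashed into the seed), so adding or re-running a stage never
perturbs the randomness of the others.  All tabular artifacts are plain CSV
with 6-significant-digit reals; rerunning an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable, read_cohort, write_cohort
from .communities import Dendrogram, fast_greedy
from .curation import CurationConfig, CuratedMatrix, apply_curation
from .minet import NetworkParams, build_network, network_to_frames
from .scoring import logistic_zscores, scores_to_frame
from .selection import SelectionResult, SplitPlan, run_selection
from .synth import BlockSpec, CohortSpec, generate_cohort

FLOAT_FMT = "%.6g"
STAGES = ("simulate", "curate", "select", "score", "network", "communities")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage-salted sub-seed (stable across runs and platforms)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    cohort_spec: CohortSpec | None = None
    cohort_path: str | None = None
    curation: CurationConfig = field(default_factory=CurationConfig)
    plan: SplitPlan = field(default_factory=SplitPlan)
    methods: tuple[str, ...] = ("rf", "lasso")
    n_trees: int = 500
    alpha: float = 0.05
    network: NetworkParams = field(default_factory=NetworkParams)
    weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_spec is None) == (self.cohort_path is None):
            raise ValueError("exactly one of cohort_spec and cohort_path must be set")
        bad = [m for m in self.methods if m not in ("rf", "lasso")]
        if bad:
            raise ValueError(f"unknown selection methods: {bad}")
        if not self.methods:
            raise ValueError("at least one selection method is required")


@dataclass
class ArmResult:
    selection: SelectionResult
    scores: list
    network: nx.Graph | None
    dendrogram: Dendrogram | None


@dataclass
class RunReport:
    outdir: Path
    artifacts: dict[str, Path]
    arms: dict[str, ArmResult]
    curated: CuratedMatrix
    summary: dict


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_to_jsonable(config: RunConfig) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(asdict(config))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute every stage and write all artifacts under ``outdir``.

    On a stage failure, partial artifacts are kept and a ``FAILED`` marker
    naming the stage is written before the error is re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    current_stage = "simulate"
    try:
        # ---- simulate / load -------------------------------------------
        if config.cohort_spec is not None:
            spec = config.cohort_spec
            if spec.seed != stage_seed(config.seed, "simulate"):
                # re-seed the spec from the master seed for reproducibility
                from dataclasses import replace

                spec = replace(spec, seed=stage_seed(config.seed, "simulate"))
            cohort, truth = generate_cohort(spec)
            path = outdir / "cohort.csv"
            write_cohort(cohort, path)
            artifacts["cohort"] = path
        else:
            cohort = read_cohort(config.cohort_path)
            truth = None

        # ---- curate ----------------------------------------------------
        current_stage = "curate"
        curated = apply_curation(cohort, config.curation)
        path = outdir / "curated.csv"
        data = curated.features.copy()
        data["outcome"] = curated.outcome
        _write_csv(data, path)
        artifacts["curated"] = path
        _write_csv(curated.ledger, outdir / "curation_ledger.csv")
        artifacts["curation_ledger"] = outdir / "curation_ledger.csv"

        arms: dict[str, ArmResult] = {}
        for method in config.methods:
            # ---- select ------------------------------------------------
            current_stage = f"select[{method}]"
            sel_seed = stage_seed(config.seed, f"select:{method}")
            from dataclasses import replace as _replace

            plan = _replace(config.plan, seed=sel_seed)
            selection = run_selection(
                curated.features,
                curated.outcome,
                method=method,
                plan=plan,
                n_trees=config.n_trees,
                seed=sel_seed,
            )
            if selection.importances is not None:
                imp = selection.importances.rename_axis("variable").reset_index()
                _write_csv(imp, outdir / f"importances_{method}.csv")
                artifacts[f"importances_{method}"] = outdir / f"importances_{method}.csv"
            sel_df = pd.DataFrame({"variable": sorted(selection.selected)})
            _write_csv(sel_df, outdir / f"selected_{method}.csv")
            artifacts[f"selected_{method}"] = outdir / f"selected_{method}.csv"
            metrics_path = outdir / f"metrics_{method}.json"
            metrics_path.write_text(
                json.dumps(
                    {
                        "method": selection.method,
                        "n_selected": len(selection.selected),
                        "threshold_or_lambda": selection.threshold,
                        **{k: selection.metrics[k] for k in sorted(selection.metrics)},
                    },
                    indent=1,
                    sort_keys=True,
                )
                + "\n"
            )
            artifacts[f"metrics_{method}"] = metrics_path

            # ---- score -------------------------------------------------
            current_stage = f"score[{method}]"
            if not selection.selected:
                warnings.warn(f"{method}: empty selection, skipping downstream stages")
                arms[method] = ArmResult(selection, [], None, None)
                continue
            scores = logistic_zscores(
                curated.features, curated.outcome, sorted(selection.selected), alpha=config.alpha
            )
            _write_csv(scores_to_frame(scores), outdir / f"scores_{method}.csv")
            artifacts[f"scores_{method}"] = outdir / f"scores_{method}.csv"

            # ---- network -----------------------------------------------
            current_stage = f"network[{method}]"
            n_signif = sum(1 for s in scores if s.available and s.significant)
            if n_signif < 2:
                warnings.warn(f"{method}: fewer than 2 significant nodes, no network")
                arms[method] = ArmResult(selection, scores, None, None)
                continue
            net_seed = stage_seed(config.seed, f"network:{method}")
            G = build_network(curated, scores, params=config.network, seed=net_seed)
            gml = outdir / f"network_{method}.graphml"
            nx.write_graphml(G, gml)
            artifacts[f"network_{method}"] = gml
            node_df, edge_df = network_to_frames(G)
            _write_csv(node_df, outdir / f"network_{method}_nodes.csv")
            _write_csv(edge_df, outdir / f"network_{method}_edges.csv")
            artifacts[f"network_{method}_nodes"] = outdir / f"network_{method}_nodes.csv"
            artifacts[f"network_{method}_edges"] = outdir / f"network_{method}_edges.csv"

            # ---- communities -------------------------------------------
            current_stage = f"communities[{method}]"
            if G.number_of_edges() == 0:
                warnings.warn(f"{method}: empty network, no communities")
                arms[method] = ArmResult(selection, scores, G, None)
                continue
            dendro = fast_greedy(G, weighted=config.weighted, weight_attr="mi")
            comm_df = pd.DataFrame(
                sorted(
                    ({"variable": n, "community": c} for n, c in dendro.partition.items()),
                    key=lambda r: (str(r["community"]), str(r["variable"])),
                )
            )
            _write_csv(comm_df, outdir / f"communities_{method}.csv")
            artifacts[f"communities_{method}"] = outdir / f"communities_{method}.csv"
            merge_df = pd.DataFrame(
                dendro.merges, columns=["community_a", "community_b", "delta_q", "q_after"]
            )
            _write_csv(merge_df, outdir / f"dendrogram_{method}.csv")
            artifacts[f"dendrogram_{method}"] = outdir / f"dendrogram_{method}.csv"

            arms[method] = ArmResult(selection, scores, G, dendro)

        # ---- manifest & report ----------------------------------------
        current_stage = "report"
        if len(arms) == 2 and all(a.dendrogram for a in arms.values()):
            comparison = compare_arms(arms["rf"], arms["lasso"])
            cmp_path = outdir / "compare_arms.json"
            cmp_path.write_text(json.dumps(comparison, indent=1, sort_keys=True) + "\n")
            artifacts["compare_arms"] = cmp_path

        manifest = {
            "config": _config_to_jsonable(config),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
            "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in sorted(artifacts.items())},
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        artifacts["manifest"] = mpath

        summary = {
            "n_records_curated": curated.n_records,
            "n_variables_curated": curated.n_variables,
            **{
                f"{m}_n_selected": len(a.selection.selected) for m, a in arms.items()
            },
            **{
                f"{m}_n_significant": sum(
                    1 for s in a.scores if s.available and s.significant
                )
                for m, a in arms.items()
            },
            **{
                f"{m}_n_edges": a.network.number_of_edges()
                for m, a in arms.items()
                if a.network is not None
            },
            **{
                f"{m}_n_communities": len(set(a.dendrogram.partition.values()))
                for m, a in arms.items()
                if a.dendrogram is not None
            },
        }
        report_lines = [f"{k} = {v}" for k, v in summary.items()]
        rpath = outdir / "report.txt"
        rpath.write_text("\n".join(report_lines) + "\n")
        artifacts["report"] = rpath
        return RunReport(outdir=outdir, artifacts=artifacts, arms=arms, curated=curated, summary=summary)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current_stage}\ncause: {exc}\n")
        raise PipelineError(current_stage, exc) from exc


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compare_arms(rf: ArmResult, lasso: ArmResult) -> dict:
    """Overlap report between the RF and Lasso arms.

    Reports the selected-set intersection/union (with Jaccard), and for each
    community of each arm the best Jaccard overlap with any community of the
    other arm's partition.
    """
    if rf is None or lasso is None:
        raise ValueError("both arms are required for comparison")
    sel_rf, sel_la = set(rf.selection.selected), set(lasso.selection.selected)
    report: dict = {
        "selected_intersection": sorted(sel_rf & sel_la),
        "selected_union": sorted(sel_rf | sel_la),
        "selected_jaccard": jaccard(sel_rf, sel_la),
    }
    if rf.dendrogram is not None and lasso.dendrogram is not None:
        comms_rf: dict = {}
        for n, c in rf.dendrogram.partition.items():
            comms_rf.setdefault(str(c), set()).add(n)
        comms_la: dict = {}
        for n, c in lasso.dendrogram.partition.items():
            comms_la.setdefault(str(c), set()).add(n)
        report["community_jaccard_rf_to_lasso"] = {
            cid: max((jaccard(mem, other) for other in comms_la.values()), default=0.0)
            for cid, mem in sorted(comms_rf.items())
        }
        report["community_jaccard_lasso_to_rf"] = {
            cid: max((jaccard(mem, other) for other in comms_rf.values()), default=0.0)
            for cid, mem in sorted(comms_la.items())
        }
    return report


# ------------------------------------------------------------ config parsing


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a plain (e.g. YAML-loaded) dictionary."""
    kwargs: dict = {}
    if "cohort_spec" in raw and raw["cohort_spec"] is not None:
        cs = dict(raw["cohort_spec"])
        blocks = tuple(BlockSpec(**b) for b in cs.pop("blocks", []))
        kwargs["cohort_spec"] = CohortSpec(blocks=blocks, **cs)
    if raw.get("cohort_path"):
        kwargs["cohort_path"] = raw["cohort_path"]
    if "curation" in raw:
        cu = dict(raw["curation"])
        for key in ("exclude_variables", "exclude_outcome_labels", "bmi_breaks"):
            if key in cu:
                cu[key] = tuple(cu[key])
        if "dichotomize_rules" in cu:
            cu["dichotomize_rules"] = {
                k: frozenset(v) for k, v in cu["dichotomize_rules"].items()
            }
        kwargs["curation"] = CurationConfig(**cu)
    if "plan" in raw:
        kwargs["plan"] = SplitPlan(**raw["plan"])
    if "network" in raw:
        kwargs["network"] = NetworkParams(**raw["network"])
    for key in ("methods", "n_trees", "alpha", "weighted", "seed"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "methods" else raw[key]
    return RunConfig(**kwargs)
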