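"""File formats, pipeline configuration and the end-to-end driver.

Canonical on-disk formats are UTF-8, tab-separated, Unix newlines (CSV
is accepted on read). Every artifact written by the pipeline embeds the
configuration hash, so a result bundle is self-describing and
re-runnable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blanket import BlanketReport, blanket_report
from .errors import FormatError, InvalidArgumentError
from .inference import (CombinationResult, EvidenceScenario, scenario_contrast,
                        simulate_scenario, top_state_combinations)
from .model import NetworkModel
from .preprocess import (CONDITION_VAR, CountMatrix, DiscreteDataset,
                         DiscretizationParams, preprocess_counts)
from .search import SearchConfig, SearchTrace, refine_and_research, run_protocol
from .synthetic import SyntheticTruth

log = logging.getLogger("piznet")


@dataclass
class PipelineConfig:
    """Every threshold and seed of the pipeline in one place.

    Defaults reproduce the study's printed settings: low-count filter
    (<10 in >=5 samples), |log2 fold change| > 2 selection, z thresholds
    at -1/+1, uniform BDe prior with ESS 1, three searches per round and
    a 15% stopping rule, with "PiZ" as the target condition variable.
    """

    min_count: int = 10
    min_samples: int = 5
    lfc_cutoff: float = 2.0
    z_low: float = -1.0
    z_high: float = 1.0
    ess: float = 1.0
    budget: int = 20000
    searches: int = 3
    improvement_threshold: float = 0.15
    max_rounds: int = 6
    max_parents: int | None = None
    seed: int = 0
    target: str = CONDITION_VAR
    genes_of_interest: tuple[str, ...] = ()
    #: extra variables clamped in the scenario contrast, e.g. {"Slc39a7": 2}
    scenario_clamp: dict = field(default_factory=dict)
    combination_k: tuple[int, ...] = (2, 3)
    #: at most this many blanket genes enter the combination analysis
    #: (mirrors the eight-gene selection from MB of the condition node)
    combination_max_candidates: int = 8

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            budget=self.budget, n_searches_per_round=self.searches,
            improvement_threshold=self.improvement_threshold,
            max_rounds=self.max_rounds, seed=self.seed,
            max_parents=self.max_parents, ess=self.ess)

    def discretization(self) -> DiscretizationParams:
        return DiscretizationParams(self.z_low, self.z_high)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes_of_interest"] = list(self.genes_of_interest)
        d["combination_k"] = list(self.combination_k)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "genes_of_interest" in d:
            d["genes_of_interest"] = tuple(d["genes_of_interest"])
        if "combination_k" in d:
            d["combination_k"] = tuple(d["combination_k"])
        return PipelineConfig(**d)

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        return PipelineConfig.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except Exception as e:  # pandas raises many parser error types
        raise FormatError(f"cannot parse {path}: {e}") from e


def read_count_matrix(path, conditions_path) -> CountMatrix:
    """Read a TSV count matrix (first column ``gene_id``) and condition map."""
    df = _read_table(path)
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', "
                          f"got {df.columns[0]!r}")
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate gene IDs: {dupes}")
    counts = df.set_index("gene_id")
    if not all(np.issubdtype(t, np.integer) for t in counts.dtypes):
        bad = [c for c, t in counts.dtypes.items() if not np.issubdtype(t, np.integer)]
        raise FormatError(f"{path}: non-integer counts in columns {bad}")
    cond_df = _read_table(conditions_path)
    if list(cond_df.columns[:2]) != ["sample_id", "condition"]:
        raise FormatError(f"{conditions_path}: expected columns sample_id, condition")
    condition = cond_df.set_index("sample_id")["condition"]
    missing = [s for s in counts.columns if s not in condition.index]
    if missing:
        raise FormatError(f"samples without condition label: {missing}")
    try:
        return CountMatrix(counts, condition)
    except InvalidArgumentError as e:
        raise FormatError(str(e)) from e


def write_count_matrix(m: CountMatrix, counts_path, conditions_path) -> None:
    out = m.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    cond = m.condition.rename("condition")
    cond.index.name = "sample_id"
    cond.to_frame().to_csv(conditions_path, sep="\t")


def read_discrete_dataset(path) -> DiscreteDataset:
    df = _read_table(path)
    if df.columns[0] != "variable":
        raise FormatError(f"{path}: first column must be 'variable'")
    return DiscreteDataset(df.set_index("variable"))


def write_discrete_dataset(data: DiscreteDataset, path, config_hash: str = "") -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        out = data.states.copy()
        out.index.name = "variable"
        out.to_csv(fh, sep="\t")


def read_gene_list(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes, path, config_hash: str = "") -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        fh.write("\n".join(genes) + "\n")


def write_model_json(model: NetworkModel, path, config_hash: str = "") -> None:
    d = model.to_dict()
    if config_hash:
        d["config_hash"] = config_hash
    Path(path).write_text(json.dumps(d, indent=1))


def read_model_json(path) -> NetworkModel:
    return NetworkModel.from_dict(json.loads(Path(path).read_text()))


def write_edges_tsv(model: NetworkModel, path, config_hash: str = "") -> None:
    """Arc list as ``parent  child  strength  sign``."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        fh.write("parent\tchild\tstrength\tsign\n")
        for (u, v) in sorted(model.structure.arcs):
            a = model.edge_annotations.get((u, v))
            strength = f"{a.strength:.6g}" if a else ""
            sign = a.sign if a else ""
            fh.write(f"{u}\t{v}\t{strength}\t{sign}\n")


def write_dot(model: NetworkModel, path, config_hash: str = "") -> None:
    """Graphviz DOT export; inhibition arcs ('-') are dashed, strength sets penwidth."""
    strengths = [a.strength for a in model.edge_annotations.values()
                 if a.strength > 0] or [1.0]
    top = max(strengths)
    lines = ["digraph piznet {"]
    if config_hash:
        lines.append(f'  // config_hash: {config_hash}')
    for v in model.structure.variables:
        lines.append(f'  "{v}";')
    for (u, v) in sorted(model.structure.arcs):
        a = model.edge_annotations.get((u, v))
        attrs = []
        if a:
            width = 1.0 + 3.0 * max(a.strength, 0.0) / top
            attrs.append(f"penwidth={width:.2f}")
            if a.sign == "-":
                attrs.append("style=dashed")
        attr = f' [{", ".join(attrs)}]' if attrs else ""
        lines.append(f'  "{u}" -> "{v}"{attr};')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trace_json(trace: SearchTrace, path, config_hash: str = "") -> None:
    d = trace.to_dict()
    if config_hash:
        d["config_hash"] = config_hash
    Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# GEO-style adapter (offline; parses a locally available counts table)
# ---------------------------------------------------------------------------

#: header spellings accepted for the gene-identifier column
GENE_ID_SYNONYMS = ("gene_id", "Geneid", "GeneID", "gene", "Gene",
                    "gene_symbol", "symbol", "Symbol", "ID", "id")


def geo_series_to_counts(path, condition_rules) -> CountMatrix:
    """Parse a GEO-supplementary-style counts table with title-pattern conditions.

    ``condition_rules`` maps regex patterns to condition labels (e.g.
    ``{"PiZ": "PiZ", "WT|wild": "wildtype"}``); each sample column title is
    assigned by the first matching pattern. A rule that matches no sample,
    or a sample no rule matches, is an error.
    """
    df = _read_table(path)
    gene_col = next((c for c in df.columns if c in GENE_ID_SYNONYMS), None)
    if gene_col is None:
        raise FormatError(
            f"{path}: no gene ID column among {GENE_ID_SYNONYMS}")
    counts = df.set_index(gene_col)
    counts = counts.select_dtypes(include="number")
    labels = {}
    matched = {pat: False for pat in condition_rules}
    for sample in counts.columns:
        for pat, label in condition_rules.items():
            if re.search(pat, sample):
                labels[sample] = label
                matched[pat] = True
                break
        else:
            raise FormatError(f"sample {sample!r} matches no condition rule")
    unmatched = [p for p, ok in matched.items() if not ok]
    if unmatched:
        raise FormatError(f"condition rules matching no sample: {unmatched}")
    try:
        return CountMatrix(counts.round().astype(int),
                           pd.Series(labels))
    except InvalidArgumentError as e:
        raise FormatError(str(e)) from e


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    config: PipelineConfig
    selected_genes: list[str]
    discrete: DiscreteDataset
    first_model: NetworkModel
    first_trace: SearchTrace
    reduced: DiscreteDataset
    final_model: NetworkModel
    final_trace: SearchTrace
    blanket: BlanketReport
    scenarios: "pd.DataFrame | None"
    combinations: list[CombinationResult]


def run_full_pipeline(config: PipelineConfig, counts: CountMatrix,
                      out_dir=None) -> PipelineResult:
    """preprocess -> learn -> blanket-refine -> relearn -> blanket/queries.

    Mirrors the study's two-pass design: learn on all selected genes,
    restrict to the target's second-degree Markov blanket plus the genes
    of interest, learn again, then read blankets, scenario marginals and
    top k-gene state combinations off the final network.
    """
    t0 = time.time()
    chash = config.hash()
    data, selected, _lfc = preprocess_counts(
        counts, genes_of_interest=config.genes_of_interest,
        min_count=config.min_count, min_samples=config.min_samples,
        lfc_cutoff=config.lfc_cutoff, params=config.discretization())
    log.info("stage=preprocess genes=%d samples=%d elapsed=%.2fs",
             len(selected), data.n_samples, time.time() - t0)

    scfg = config.search_config()
    t1 = time.time()
    first_model, first_trace = run_protocol(data, scfg)
    log.info("stage=learn1 vars=%d rounds=%d norm=%.5f elapsed=%.2fs",
             len(data.variables), len(first_trace.rounds),
             first_model.normalized_score, time.time() - t1)

    t2 = time.time()
    reduced, final_model, final_trace = refine_and_research(
        data, first_model, config.target, config.genes_of_interest, scfg)
    log.info("stage=learn2 vars=%d rounds=%d norm=%.5f elapsed=%.2fs",
             len(reduced.variables), len(final_trace.rounds),
             final_model.normalized_score, time.time() - t2)

    report = blanket_report(final_model.structure, config.target)

    scenarios = None
    if config.target in final_model.structure.index:
        a = EvidenceScenario({config.target: 1, **config.scenario_clamp})
        b = EvidenceScenario({config.target: 0, **config.scenario_clamp})
        scenarios = scenario_contrast(final_model, a, b)

    candidates = sorted(report.first_degree)[:config.combination_max_candidates]
    combos = []
    for k in config.combination_k:
        if len(candidates) >= k:
            combos.append(top_state_combinations(
                final_model, candidates, k, {config.target: 1}))

    result = PipelineResult(config, selected, data, first_model, first_trace,
                            reduced, final_model, final_trace, report,
                            scenarios, combos)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), chash)
    log.info("stage=pipeline elapsed=%.2fs", time.time() - t0)
    return result


def _write_bundle(result: PipelineResult, out: Path, chash: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(
        {**result.config.to_dict(), "config_hash": chash}))
    write_gene_list(result.selected_genes, out / "selected_genes.txt", chash)
    write_discrete_dataset(result.discrete, out / "discrete.tsv", chash)
    write_model_json(result.first_model, out / "first_model.json", chash)
    write_trace_json(result.first_trace, out / "first_trace.json", chash)
    write_discrete_dataset(result.reduced, out / "reduced.tsv", chash)
    write_model_json(result.final_model, out / "final_model.json", chash)
    write_trace_json(result.final_trace, out / "final_trace.json", chash)
    write_edges_tsv(result.final_model, out / "final_edges.tsv", chash)
    write_dot(result.final_model, out / "final_model.dot", chash)
    blanket_d = result.blanket.to_dict()
    blanket_d["config_hash"] = chash
    (out / "blanket.json").write_text(json.dumps(blanket_d, indent=1))
    if result.scenarios is not None:
        with open(out / "scenarios.tsv", "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            result.scenarios.to_csv(fh, sep="\t")
    combos_d = {"config_hash": chash,
                "results": [{"k": c.k, "condition": c.condition,
                             "rows": c.to_rows()[:50]} for c in result.combinations]}
    (out / "combinations.json").write_text(json.dumps(combos_d, indent=1))


def write_truth_json(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth_json(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
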