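"""End-to-end pipeline: load -> DE -> group -> kernel -> score -> evaluate.

The :class:`RunConfig` gathers every tunable parameter with its default, can
be populated from a TOML config file with CLI-style flat keys, and is
serialized alongside every output directory so a run can be reproduced
exactly.  For fixed inputs and seeds the pipeline is deterministic: rerunning
a command produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import evaluation as ev
from .expression import DEResult, ExpressionMatrix, de_test, load_expression
from .grouping import (GeneGroup, GroupTable, cluster_groups,
                       correlation_distance)
from .network import PPINetwork, kernel_for_network, load_ppi
from .scoring import (RankingResult, ScoringParams, rank_candidates,
                      ranking_to_frame, single_rank)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults."""

    expr: str | None = None
    labels: str | None = None
    ppi: str | None = None
    candidates: str | None = None   # optional candidate list file
    known: str | None = None        # known disease-gene list file

    distance: float = 0.3           # clustering cut threshold d
    distance_mode: str = "signed"   # "signed" (1-r)/2 | "abs" 1-|r|
    gamma: float = 1.0              # kernel diffusion rate
    iters: int = 5                  # kernel iterations
    alpha: float = 15.0             # hub penalization
    beta: float = 20.0              # group-size penalization
    alpha_de: float = 0.05          # Bonferroni-corrected DE threshold
    penalty: str = "cap"            # "cap" | "exp"
    linear: bool = False            # expression on linear scale
    drop_singletons: bool = False
    null_resamples: int = 1000
    seed: int = 0

    provenance: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path, **cli_overrides) -> "RunConfig":
        """Load a flat TOML config; explicit CLI values override the file."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        valid = {f.name for f in dataclasses.fields(cls)} - {"provenance"}
        for key, val in data.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r} in {path}")
            setattr(cfg, key, val)
            cfg.provenance[key] = "config-file"
        for key, val in cli_overrides.items():
            if val is not None:
                setattr(cfg, key, val)
                cfg.provenance[key] = "cli"
        return cfg

    def scoring_params(self) -> ScoringParams:
        return ScoringParams(alpha=self.alpha, beta=self.beta,
                             gamma=self.gamma, n_iter=self.iters,
                             penalty=self.penalty)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        prov = d.pop("provenance")
        d["provenance"] = {
            k: prov.get(k, "default") for k in sorted(d)
        }
        d["schema_version"] = SCHEMA_VERSION
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PipelineState:
    """Intermediate artifacts shared across pipeline stages."""

    network: PPINetwork
    expression: ExpressionMatrix
    de: DEResult
    kernel: object
    groups: list[GeneGroup]
    candidates: list[str]


def _read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh
                if line.strip() and not line.startswith("#")]


def prepare(config: RunConfig,
            network: PPINetwork | None = None,
            expression: ExpressionMatrix | None = None) -> PipelineState:
    """Run the shared stages (load, DE, kernel, grouping) once."""
    try:
        if network is None:
            if config.ppi is None:
                raise ValueError("no PPI network given")
            network = load_ppi(config.ppi)
    except Exception as exc:
        raise RuntimeError(f"[network stage] {exc}; check --ppi") from exc
    try:
        if expression is None:
            if config.expr is None or config.labels is None:
                raise ValueError("no expression matrix / labels given")
            expression = load_expression(config.expr, config.labels)
    except Exception as exc:
        raise RuntimeError(
            f"[expression stage] {exc}; check --expr/--labels"
        ) from exc

    de = de_test(expression, alpha=config.alpha_de, linear=config.linear)
    kernel = kernel_for_network(network, gamma=config.gamma,
                                n_iter=config.iters)

    de_genes = [g for g in de.de_genes if g in network]
    if len(de_genes) >= 2:
        dist = correlation_distance(expression, de_genes,
                                    mode=config.distance_mode)
        groups = cluster_groups(dist, config.distance, de=de,
                                drop_singletons=config.drop_singletons)
    elif de_genes:
        groups = cluster_groups_singleton(de_genes, de)
    else:
        logger.warning("no DE genes in the network: rankings will be flat")
        groups = []

    if config.candidates:
        candidates = _read_gene_list(config.candidates)
    else:
        known = set(_read_gene_list(config.known)) if config.known else set()
        candidates = list(network.nodes)
        # known genes stay in the candidate set: they are evaluated as
        # ordinary candidates (leave-one-in), since no training set exists
        del known
    logger.info("pipeline: %d genes, %d DE, %d groups at d=%.2f, "
                "%d candidates", len(expression.genes), len(de.de_genes),
                len(groups), config.distance, len(candidates))
    return PipelineState(network=network, expression=expression, de=de,
                         kernel=kernel, groups=groups, candidates=candidates)


def cluster_groups_singleton(de_genes, de) -> list[GeneGroup]:
    from .scoring import group_expression_level

    groups = [GeneGroup(members=[g], group_id=f"group_{i + 1}")
              for i, g in enumerate(sorted(de_genes))]
    for g in groups:
        group_expression_level(g, de)
    return groups


def run_pipeline(
    config: RunConfig,
    network: PPINetwork | None = None,
    expression: ExpressionMatrix | None = None,
    baseline: bool = False,
) -> tuple[RankingResult, ev.EvaluationReport | None, PipelineState]:
    """Execute the full pipeline; evaluate if a known-gene list is given.

    With ``baseline=True`` the SingleRank degenerate scoring (one singleton
    group per DE gene) replaces the co-expressed grouping.
    """
    state = prepare(config, network=network, expression=expression)
    params = config.scoring_params()
    if baseline:
        ranking = single_rank(state.candidates, state.de, state.kernel,
                              state.network, params)
    else:
        ranking = rank_candidates(state.candidates, state.groups,
                                  state.kernel, state.network, state.de,
                                  params)
    report = None
    if config.known:
        report = ev.evaluate(ranking, _read_gene_list(config.known))
    return ranking, report, state


def write_outputs(outdir, config: RunConfig, ranking: RankingResult,
                  report=None, state: PipelineState | None = None) -> None:
    """Persist ranking, contributions, groups, report and effective config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# grouprank schema_version={SCHEMA_VERSION}\n"

    with open(outdir / "ranking.tsv", "w") as fh:
        fh.write(header)
        ranking_to_frame(ranking).to_csv(fh, sep="\t", index=False,
                                         float_format="%.10g")
    with open(outdir / "contributions.tsv", "w") as fh:
        fh.write(header)
        ranking.contributions.to_csv(fh, sep="\t", float_format="%.10g")
    if state is not None:
        with open(outdir / "groups.tsv", "w") as fh:
            fh.write(header)
            GroupTable(state.groups).to_frame().to_csv(
                fh, sep="\t", index=False, float_format="%.10g")
    if report is not None:
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    (outdir / "config.json").write_text(config.to_json())
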