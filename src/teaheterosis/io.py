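"""Readers/writers for the pipeline's TSV/GMT formats, run config, pipeline.

All tables are UTF-8 TSV with '.' decimal separators; gene ids are opaque
strings.  ``run_pipeline`` chains classification -> summary -> optional SOM
co-module screening -> correlation -> ORA and writes a JSON manifest so an
identical config on identical inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .patterns import (
    ExpressionMatrix,
    ROLES,
    classify_matrix_with_calls,
    summarize_patterns,
)
from .coexpression import (
    assign_modules,
    co_module_candidates,
    correlation_matrix,
    train_som,
    zscore_profiles,
)
from .enrichment import TermMap, ora
from .volatiles import VolatileTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrix TSV
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a sample sheet into a validated matrix.

    The sample sheet needs columns sample_id, genotype_role, replicate; the
    matrix header must match its sample ids.
    """
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype_role", "replicate"}
    if not required <= set(sheet.columns):
        raise ValueError(
            f"sample sheet missing columns: {sorted(required - set(sheet.columns))}"
        )
    sheet = sheet.set_index("sample_id")
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {matrix_path.name}: {dup!r}")
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[~values[col].apply(lambda v: isinstance(v, (int, float)))]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in column {col!r} (e.g. row {row!r})"
            )
    missing_roles = [r for r in ROLES if r not in set(sheet["genotype_role"])]
    if missing_roles:
        raise ValueError("role " + ", ".join(missing_roles) + " absent")
    unknown = set(values.columns) - set(sheet.index)
    if unknown:
        raise ValueError(f"matrix samples absent from sample sheet: {sorted(unknown)}")
    return ExpressionMatrix(values=values, design=sheet)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     sample_sheet_path: str | Path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    matrix.design.rename_axis("sample_id").to_csv(sample_sheet_path, sep="\t")


def write_truth(truth: dict[str, str], path: str | Path) -> None:
    pd.Series(truth, name="class").rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth(path: str | Path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col=0)["class"]
    return {str(k): str(v) for k, v in s.items()}


# ---------------------------------------------------------------------------
# volatile table TSV
# ---------------------------------------------------------------------------

def read_volatiles(path: str | Path) -> VolatileTable:
    """Read a long- or wide-format volatile TSV.

    Long format: compound, compound_class, genotype, replicate,
    concentration.  Wide format: compound, compound_class, genotype,
    rep1..repN columns.
    """
    df = pd.read_csv(path, sep="\t")
    if "concentration" in df.columns:
        return VolatileTable(df)
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValueError(
            "volatile table needs either a 'concentration' column or rep1..repN columns"
        )
    long = df.melt(
        id_vars=[c for c in df.columns if c not in rep_cols],
        value_vars=rep_cols,
        var_name="replicate",
        value_name="concentration",
    )
    long["replicate"] = long["replicate"].str.removeprefix("rep").astype(int)
    return VolatileTable(long)


def write_volatiles(table: VolatileTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT term maps and id lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, background: set[str] | None = None) -> TermMap:
    """Read a GMT file (term, description, members...).

    Without an explicit background, the union of all term members is used.
    """
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        term, desc, members = parts[0], parts[1], parts[2:]
        terms[term] = {m for m in members if m}
        names[term] = desc or term
    if background is None:
        background = set().union(*terms.values()) if terms else set()
    return TermMap(terms=terms, background=background, names=names)


def read_id_list(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


# ---------------------------------------------------------------------------
# run configuration + pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline settings (thresholds, SOM grid, paths)."""

    matrix_path: str
    sample_sheet_path: str
    out_dir: str
    alpha: float = 0.05
    fc_min: float = 2.0
    pseudocount: float = 0.1
    use_q: bool = False
    som_rows: int = 2
    som_cols: int = 4
    som_epochs: int = 20
    seed: int = 0
    run_som: bool = True
    anchors_path: str | None = None
    tfs_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.som_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.som_rows < 1 or self.som_cols < 1:
            raise ValueError("SOM grid must have at least one unit")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts under out_dir.

    Stages: classify -> summarize -> (SOM -> co-modules -> correlation) ->
    (ORA).  Returns the manifest dict (also written as manifest.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_expression"
    try:
        matrix = read_expression(config.matrix_path, config.sample_sheet_path)
        log.info("loaded %d genes x %d samples", *matrix.values.shape)

        stage = "classify"
        assignments, calls = classify_matrix_with_calls(
            matrix,
            alpha=config.alpha,
            fc_min=config.fc_min,
            pseudocount=config.pseudocount,
            use_q=config.use_q,
        )
        calls.to_csv(out / "assignments.tsv", sep="\t")

        stage = "summarize"
        summary = summarize_patterns(assignments)
        (out / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        log.info(
            "classified %d genes: %d non-additive, %d additive",
            summary.n_genes, summary.n_non_additive, summary.n_additive,
        )

        outputs = ["assignments.tsv", "summary.json"]
        if config.run_som:
            stage = "som"
            up_clusters = {"C5", "C6", "C9"}  # higher expression in the F1s
            up_genes = [a.gene_id for a in assignments if a.cluster in up_clusters]
            log.info("%d F1-upregulated genes enter SOM clustering", len(up_genes))
            if up_genes:
                profiles = zscore_profiles(matrix.role_means().loc[up_genes])
                model = train_som(
                    profiles,
                    rows=config.som_rows,
                    cols=config.som_cols,
                    epochs=config.som_epochs,
                    seed=config.seed,
                )
                assignment = assign_modules(model, profiles)
                pd.DataFrame(
                    {
                        "gene_id": list(assignment.unit_of),
                        "unit": list(assignment.unit_of.values()),
                    }
                ).to_csv(out / "modules.tsv", sep="\t", index=False)
                pd.DataFrame(
                    model.codebook,
                    columns=list(ROLES),
                ).rename_axis("unit").to_csv(out / "codebook.tsv", sep="\t")
                outputs += ["modules.tsv", "codebook.tsv"]
                if config.anchors_path and config.tfs_path:
                    stage = "co_modules"
                    anchors = read_id_list(config.anchors_path) & set(
                        assignment.unit_of
                    )
                    tfs = read_id_list(config.tfs_path)
                    cands = co_module_candidates(assignment, anchors, tfs)
                    pd.DataFrame(
                        [
                            {"anchor": a, "tf": t}
                            for a, ts in sorted(cands.items())
                            for t in sorted(ts)
                        ],
                        columns=["anchor", "tf"],
                    ).to_csv(out / "co_module_tfs.tsv", sep="\t", index=False)
                    outputs.append("co_module_tfs.tsv")
                    stage = "correlation"
                    corr_ids = sorted(anchors | set().union(*cands.values(), set()))
                    if len(corr_ids) >= 2:
                        corr = correlation_matrix(matrix.role_means().loc[corr_ids])
                        corr.to_long().to_csv(
                            out / "correlations.tsv", sep="\t", index=False
                        )
                        outputs.append("correlations.tsv")

        if config.gmt_path:
            stage = "ora"
            term_map = read_gmt(config.gmt_path)
            query = {
                a.gene_id
                for a in assignments
                if a.category in ("higher-parent dominance", "up-overdominance")
            }
            query &= term_map.background
            if query:
                rows = ora(query, term_map)
                pd.DataFrame(
                    [
                        {
                            "term_id": r.term_id,
                            "term_name": r.term_name,
                            "gene_ratio": r.gene_ratio,
                            "p_value": r.p,
                            "fdr": r.fdr,
                        }
                        for r in rows
                    ]
                ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
                outputs.append("enrichment.tsv")
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
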