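"""Relative gene expression from Ct tables (Livak 2^-ddCt method).

Per biological sample, dCt = Ct(gene) - Ct(reference gene, ACTB by default);
ddCt = dCt - mean dCt of the untreated samples of that gene; the fold change
is 2^-ddCt.  Technical replicate Cts, when present, are averaged per
biological sample first, so each sample contributes one dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "gene", "condition", "Ct")


def load_reference_primers() -> pd.DataFrame:
    """Reference qPCR primer table (gene, direction, sequence) for the human
    interferon-response genes this assay panel targets, plus the ACTB
    housekeeping reference."""
    from importlib.resources import files

    with files("focusq.data").joinpath("primers.csv").open() as fh:
        return pd.read_csv(fh)


def relative_expression(
    table: pd.DataFrame,
    reference_gene: str = "ACTB",
    untreated_label: str = "untreated",
    pool_experiments: bool = False,
) -> pd.DataFrame:
    """Compute dCt, ddCt and 2^-ddCt fold change per sample and gene.

    Parameters
    ----------
    table
        Long-format Ct table with columns ``sample``, ``gene``, ``condition``
        and ``Ct`` (cycles); an optional ``experiment`` column identifies
        independent experiments.  Repeated (sample, gene) rows are treated as
        technical replicates and averaged.
    reference_gene
        Housekeeping gene used for dCt (beta-actin by default).
    untreated_label
        Condition label of the baseline group; its mean dCt per gene anchors
        ddCt.
    pool_experiments
        When an ``experiment`` column is present, normalise against the
        untreated mean of the same experiment (default) or of all experiments
        pooled.

    Raises
    ------
    ValueError
        If a gene has no untreated samples, naming the gene, or a sample
        lacks a reference-gene Ct, naming the sample.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks required columns: {missing}")
    df = table.copy()
    has_experiment = "experiment" in df.columns and not pool_experiments
    group_cols = ["sample", "gene", "condition"] + (
        ["experiment"] if "experiment" in df.columns else []
    )
    # technical replicates -> one Ct per biological sample and gene
    df = df.groupby(group_cols, sort=False, as_index=False)["Ct"].mean()

    ref = df[df["gene"] == reference_gene].set_index("sample")["Ct"]
    if ref.index.has_duplicates:
        ref = ref.groupby(level=0).mean()
    goi = df[df["gene"] != reference_gene].copy()
    unmatched = sorted(set(goi["sample"]) - set(ref.index))
    if unmatched:
        raise ValueError(
            f"samples without a {reference_gene} reference Ct: {unmatched}"
        )
    goi["dCt"] = goi["Ct"].to_numpy() - ref.loc[goi["sample"]].to_numpy()

    baseline_cols = ["gene"] + (["experiment"] if has_experiment else [])
    untreated = goi[goi["condition"] == untreated_label]
    no_baseline = sorted(set(goi["gene"]) - set(untreated["gene"]))
    if no_baseline:
        raise ValueError(f"genes with no untreated samples: {no_baseline}")
    baseline = untreated.groupby(baseline_cols)["dCt"].mean().rename("baseline_dCt")
    goi = goi.merge(baseline.reset_index(), on=baseline_cols, how="left")
    if goi["baseline_dCt"].isna().any():
        bad = goi.loc[goi["baseline_dCt"].isna(), baseline_cols].drop_duplicates()
        raise ValueError(f"no untreated baseline for: {bad.to_dict('records')}")
    goi["ddCt"] = goi["dCt"] - goi["baseline_dCt"]
    goi["fold"] = np.exp2(-goi["ddCt"])
    return goi.drop(columns=["baseline_dCt"]).reset_index(drop=True)
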