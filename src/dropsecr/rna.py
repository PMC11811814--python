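"""Rule-based scRNA-seq gating: subsets, NOX_mRNA status, DEGs, pathways.

Works on a cells x genes matrix of log2 fold changes versus a pooled
reference. Cells are assigned to B-lineage subsets by the mean log2FC
over subset marker genes (argmax); NOX_mRNA status is positive when any
gene of the NOX gene set (isoforms, regulators and complex subunits) has
log2FC > 0 and negative when all are <= 0. Differential expression uses
a two-sided rank-sum test with raw p-values filtered at 0.05 downstream;
pathway modulation is the signed mean log2FC of the pathway's DEGs.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: NOX isoforms, regulators and complex-subunit genes used for the
#: NOX_mRNA positive/negative split.
NOX_GENE_SET = (
    "NOX1", "NOX2", "NOX3", "NOX4", "DUOX1", "DUOX2",
    "NOXO1", "NOXA1", "CYBA", "CYBB", "NCF1", "NCF2", "NCF4",
    "DUOXA1", "DUOXA2",
)

#: internal-control genes expected to show no condition effect
HOUSEKEEPING_GENES = (
    "ATF1", "ATF2", "ATF4", "ATF6", "ATF7",
    "BTF3", "E2F4", "JUND", "HPRT", "RPL3",
)

LABEL_POS = "pos"
LABEL_NEG = "neg"
UNASSIGNED = "unassigned"


def default_marker_config() -> dict:
    """Bundled marker config (subsets, GC zones, PC states).

    These are generic literature-style mouse B-cell markers shipped as an
    editable starting point; studies should substitute their own marker
    tables via YAML.
    """
    ref = resources.files("dropsecr").joinpath("data/markers.yaml")
    return yaml.safe_load(ref.read_text())


def default_pathways() -> dict[str, list[str]]:
    """Bundled metabolic/signaling pathway gene sets (editable YAML)."""
    ref = resources.files("dropsecr").joinpath("data/pathways.yaml")
    return yaml.safe_load(ref.read_text())


def load_matrix(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Read a cells x genes matrix from dense CSV or MTX + TSV sidecars."""
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        m = mmread(path).toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
        return pd.DataFrame(m, index=cells, columns=genes)
    return pd.read_csv(path, index_col=0)


def _set_values(matrix: pd.DataFrame, gene_set) -> pd.DataFrame:
    present = [g for g in gene_set if g in matrix.columns]
    missing = [g for g in gene_set if g not in matrix.columns]
    if missing:
        warnings.warn(f"genes missing from matrix (treated as 0): {missing}")
    vals = matrix.reindex(columns=list(gene_set), fill_value=0.0)
    if not present:
        raise ValueError("no genes of the set present in the matrix")
    return vals


def classify_nox_mrna(
    values: pd.DataFrame | pd.Series,
    gene_set=NOX_GENE_SET,
    mode: str = "any",
) -> pd.Series | str:
    """NOX_mRNA status from log2FC values over the NOX gene set.

    ``mode="any"`` (default): positive iff any set gene is > 0 — a cell
    expressing a single isoform above the pooled reference counts as
    positive. ``mode="mean"`` aggregates the set mean instead.
    """
    if len(tuple(gene_set)) == 0:
        raise ValueError("empty NOX gene set")
    single = isinstance(values, pd.Series)
    df = values.to_frame().T if single else values
    vals = _set_values(df, tuple(gene_set))
    if mode == "any":
        pos = (vals > 0).any(axis=1)
    elif mode == "mean":
        pos = vals.mean(axis=1) > 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = pos.map({True: LABEL_POS, False: LABEL_NEG})
    return labels.iloc[0] if single else labels


def assign_subset(matrix: pd.DataFrame, marker_config: dict) -> pd.Series:
    """Argmax-of-mean-marker-score subset assignment.

    Ties and cells whose best score is <= 0 are labeled ``unassigned``.
    """
    subsets = marker_config["subsets"] if "subsets" in marker_config else marker_config
    scores = pd.DataFrame(index=matrix.index)
    for name, markers in subsets.items():
        vals = matrix.reindex(columns=list(markers), fill_value=0.0)
        missing = [g for g in markers if g not in matrix.columns]
        if missing:
            warnings.warn(f"markers missing for {name} (treated as 0): {missing}")
        scores[name] = vals.mean(axis=1)
    arr = scores.to_numpy()
    best = arr.max(axis=1)
    # a tie for the best score -> unassigned
    tied = (arr == best[:, None]).sum(axis=1) > 1
    labels = pd.Series(scores.columns[arr.argmax(axis=1)], index=matrix.index)
    labels[(best <= 0) | tied] = UNASSIGNED
    return labels


def deg_test(group: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-gene log2FC and rank-sum p-value of a group versus the pooled
    reference. No multiplicity adjustment; the 0.05 filter is applied by
    the caller (an optional BH column is provided for convenience)."""
    if group.empty or reference.empty:
        raise ValueError("both groups must be non-empty")
    common = group.columns.intersection(reference.columns)
    g = group[common].to_numpy()
    r = reference[common].to_numpy()
    log2fc = g.mean(axis=0) - r.mean(axis=0)
    with np.errstate(all="ignore"):
        res = sps.mannwhitneyu(g, r, axis=0, method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    # constant gene in both groups: no evidence either way
    const = (g.std(axis=0) == 0) & (r.std(axis=0) == 0) & (g[0] == r[0])
    p[const | ~np.isfinite(p)] = 1.0
    out = pd.DataFrame({"gene": common, "log2fc": log2fc, "p": p})
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def pathway_modulation(deg_table: pd.DataFrame, pathway_genes, p_max: float = 0.05):
    """Signed modulation score of one pathway: mean log2FC over the
    pathway's differentially expressed genes (p < ``p_max``).

    Returns ``(score, direction)`` with direction in
    {"positive", "negative", "none", "no call"}.
    """
    degs = deg_table[deg_table["p"] < p_max]
    hit = degs[degs["gene"].isin(set(pathway_genes))]
    if hit.empty:
        return float("nan"), "no call"
    score = float(hit["log2fc"].mean())
    if score > 0:
        return score, "positive"
    if score < 0:
        return score, "negative"
    return score, "none"


def composition_report(annotations: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Frequency tables from per-cell annotations.

    Produces subset fractions per day, the NOX_mRNA-positive fraction per
    subset and day, the DZ/LZ split among NOX-positive GC B cells, the
    plasma-cell state split, and IGHG-expresser fractions, each with
    explicit denominators (zero denominators stay NaN).
    """

    def fractions(df, key):
        counts = df.groupby(["day", key], observed=True).size().rename("n").reset_index()
        totals = counts.groupby("day")["n"].transform("sum")
        counts["fraction"] = counts["n"] / totals
        counts["denominator"] = totals
        return counts

    out = {"subsets": fractions(annotations, "subset")}

    nox = (
        annotations.groupby(["day", "subset"], observed=True)["nox_mrna"]
        .agg(n_pos=lambda s: int((s == LABEL_POS).sum()), denominator="size")
        .reset_index()
    )
    nox["fraction_pos"] = nox["n_pos"] / nox["denominator"]
    out["nox_by_subset"] = nox

    if "zone" in annotations.columns:
        gc_pos = annotations[
            (annotations["subset"] == "gcbc")
            & (annotations["nox_mrna"] == LABEL_POS)
            & (annotations["zone"] != "")
        ]
        if len(gc_pos):
            out["dz_lz_among_nox_pos_gcbc"] = fractions(gc_pos, "zone")
    if "pc_state" in annotations.columns:
        pcs = annotations[
            (annotations["subset"] == "plasma_cell") & (annotations["pc_state"] != "")
        ]
        if len(pcs):
            out["pc_states"] = fractions(pcs, "pc_state")
    if "ighg_expresser" in annotations.columns:
        pcs = annotations[annotations["subset"] == "plasma_cell"]
        if len(pcs):
            igg = (
                pcs.groupby(["day", "nox_mrna"], observed=True)["ighg_expresser"]
                .agg(n_expresser="sum", denominator="size")
                .reset_index()
            )
            igg["fraction"] = igg["n_expresser"] / igg["denominator"]
            out["ighg_expressers"] = igg
    return out


def housekeeping_check(
    matrix: pd.DataFrame,
    genes=HOUSEKEEPING_GENES,
    tolerance: float = 0.25,
) -> tuple[bool, pd.DataFrame]:
    """Internal control: housekeeping genes must stay unmodulated.

    Passes iff every housekeeping gene's |mean log2FC| is below
    ``tolerance`` and none deviates from 0 by a Wilcoxon signed-rank test
    after Benjamini-Hochberg adjustment across the control genes.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    present = [g for g in genes if g in matrix.columns]
    missing = [g for g in genes if g not in matrix.columns]
    if not present:
        raise ValueError("no housekeeping genes present")
    rows = []
    for g in present:
        vals = matrix[g].to_numpy(dtype=float)
        if np.allclose(vals, 0.0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(vals)[1])
        rows.append({"gene": g, "mean_log2fc": float(vals.mean()), "p": p})
    table = pd.DataFrame(rows)
    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table["ok"] = (table["mean_log2fc"].abs() < tolerance) & (table["p_bh"] >= 0.05)
    table["missing"] = False
    for g in missing:
        table.loc[len(table)] = {
            "gene": g, "mean_log2fc": float("nan"), "p": float("nan"),
            "p_bh": float("nan"), "ok": True, "missing": True,
        }
    passed = bool(table["ok"].all())
    return passed, table
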