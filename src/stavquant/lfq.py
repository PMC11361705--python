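"""Proximity-labelling LFQ enrichment workflow.

Implements the standard label-free-quantification contrast used for
TurboID/BioID experiments: filter protein groups for at least one
valid value in the bait group, log2-transform, impute missing values
from a per-sample normal distribution downshifted toward the
detection limit (mean - 1.8 SD, width 0.3 SD — the usual Perseus
convention), run an unpaired Student's t-test of each bait group
against the untagged control triplicate, report the t-test difference
(mean log2 bait - mean log2 control), bin differences into enrichment
increments, and map the results onto a named parts list (nucleoporins
and transport factors of the trypanosome nuclear pore complex).
"""

from __future__ import annotations

import importlib.resources
import re
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImputeParams",
    "read_lfq_tsv",
    "read_group_map",
    "filter_valid",
    "log2_transform",
    "impute",
    "ttest_vs_control",
    "bin_increments",
    "load_components",
    "map_components",
    "run_enrichment",
]

_LFQ_HEADER = re.compile(r"^LFQ intensity\s+(.+)$", re.IGNORECASE)


@dataclass(frozen=True)
class ImputeParams:
    """Downshifted-normal imputation parameters (units of per-sample SD)."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


# --------------------------------------------------------------------------
# I/O

def read_lfq_tsv(path) -> pd.DataFrame:
    """Read an LFQ table: first column protein-group ID, rest intensities.

    MaxQuant-style ``LFQ intensity <sample>`` headers are normalised to
    the bare sample name.  Empty cells and zeros are treated as missing
    (MaxQuant reports non-quantified proteins as 0).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "protein_group"
    df.columns = [
        (_LFQ_HEADER.match(c).group(1) if _LFQ_HEADER.match(c) else c) for c in df.columns
    ]
    if df.columns.duplicated().any():
        raise ValueError("sample names must be unique")
    df = df.apply(pd.to_numeric, errors="coerce")
    return df.replace(0.0, np.nan)


def read_group_map(path) -> tuple[dict[str, list[str]], str]:
    """Read a YAML sample->group map: {groups: {name: [samples]}, control: name}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = {str(g): [str(s) for s in samples] for g, samples in doc["groups"].items()}
    control = str(doc["control"])
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups {sorted(groups)}")
    return groups, control


# --------------------------------------------------------------------------
# Workflow steps

def filter_valid(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    bait_group: str,
    min_valid: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep protein groups with >= ``min_valid`` quantified bait replicates.

    Returns the filtered table and the list of removed protein IDs.
    """
    if bait_group not in groups:
        raise ValueError(f"unknown bait group {bait_group!r}")
    bait_cols = groups[bait_group]
    if min_valid > len(bait_cols):
        import warnings

        warnings.warn(
            f"min_valid={min_valid} exceeds bait group size {len(bait_cols)}; "
            "all rows will be removed"
        )
    n_valid = table[bait_cols].notna().sum(axis=1)
    keep = n_valid >= min_valid
    removed = table.index[~keep].tolist()
    return table.loc[keep].copy(), removed


def log2_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of raw intensities; missing values stay missing."""
    bad = (table <= 0).any(axis=None)
    if bad:
        rows, cols = np.nonzero((table <= 0).to_numpy())
        r, c = rows[0], cols[0]
        raise ValueError(
            f"non-positive intensity at protein {table.index[r]!r}, "
            f"sample {table.columns[c]!r}; raw LFQ intensities must be > 0"
        )
    return np.log2(table)


def _cell_normal(seed: int, row: str, col: str) -> float:
    """Standard-normal draw keyed by (seed, row, column) identity."""
    rng = np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(str(col).encode()), zlib.crc32(str(row).encode())]
    )
    return float(rng.standard_normal())


def impute(table: pd.DataFrame, params: ImputeParams = ImputeParams()) -> pd.DataFrame:
    """Impute missing log2 intensities from a downshifted normal.

    Per sample column, the mean mu and SD sigma (ddof=1) of the observed
    values are computed and every missing cell is drawn from
    Normal(mu - downshift*sigma, (width*sigma)^2).  Draws are keyed by
    (seed, sample, protein) so the result is independent of row and
    column order.  Columns with fewer than 3 observed values raise
    (sigma cannot be estimated reliably).
    """
    out = table.copy()
    for col in table.columns:
        observed = table[col].dropna()
        missing_idx = table.index[table[col].isna()]
        if missing_idx.empty:
            continue
        if observed.size < 3:
            raise ValueError(
                f"sample {col!r} has only {observed.size} observed values; "
                "cannot estimate the detection-limit distribution"
            )
        mu = float(observed.mean())
        sigma = float(observed.std(ddof=1))
        centre = mu - params.downshift * sigma
        width = params.width * sigma
        draws = [
            centre + width * _cell_normal(params.seed, row, col) for row in missing_idx
        ]
        out.loc[missing_idx, col] = draws
    return out


def ttest_vs_control(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    bait_group: str,
    control_group: str,
    test: str = "student",
) -> pd.DataFrame:
    """Per-protein unpaired two-tailed t-test of bait against control.

    The table must be log2-transformed and fully imputed.  Returns a
    frame with ``t_test_difference`` (mean bait - mean control),
    ``t_statistic``, ``p_value``, a Benjamini-Hochberg ``q_value``
    column for convenience, and a ``flag`` column ("degenerate
    variance" when the pooled variance is zero with a non-zero
    difference; identical groups give p = 1).
    """
    for g in (bait_group, control_group):
        if g not in groups:
            raise ValueError(f"unknown group {g!r}")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples for a t-test")
    a = table[groups[bait_group]].to_numpy(dtype=float)
    b = table[groups[control_group]].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values remain; impute before testing")
    diff = a.mean(axis=1) - b.mean(axis=1)
    import warnings

    with warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; they are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    flags = np.full(diff.shape, "", dtype=object)
    degenerate = ~np.isfinite(t_stat)
    zero_diff = degenerate & (diff == 0.0)
    p[zero_diff] = 1.0
    t_stat[zero_diff] = 0.0
    p[degenerate & ~zero_diff] = np.nan
    flags[degenerate & ~zero_diff] = "degenerate variance"
    finite = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "t_test_difference": diff,
            "t_statistic": t_stat,
            "p_value": p,
            "q_value": q,
            "flag": flags,
        },
        index=table.index,
    )


NOT_ENRICHED = 0


def bin_increments(
    results: pd.DataFrame, edges: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0)
) -> pd.DataFrame:
    """Bin t-test differences into enrichment increment classes.

    Classes are counted from 1 for the half-open interval
    [edge_1, edge_2), so a difference exactly on an edge falls in the
    upper interval; differences below the lowest edge get class 0,
    labelled "not enriched".
    """
    e = np.asarray(edges, dtype=float)
    if e.size < 1 or not np.all(np.diff(e) > 0):
        raise ValueError("edges must be strictly increasing")
    out = results.copy()
    cls = np.searchsorted(e, out["t_test_difference"].to_numpy(), side="right")
    out["increment_class"] = cls
    out["increment_label"] = [
        "not enriched" if c == NOT_ENRICHED else f"class {c}" for c in cls
    ]
    return out


# --------------------------------------------------------------------------
# Component mapping

def load_components(path=None) -> pd.DataFrame:
    """Load a component parts list (TSV: component, gene_id, substructure, synonyms).

    Without ``path``, the bundled trypanosome nuclear-pore parts list is
    used (nucleoporins and transport factors by name; gene IDs where
    established, e.g. exportin 1 = Tb927.11.14340).
    """
    if path is None:
        path = importlib.resources.files("stavquant").joinpath("data/npc_components.tsv")
    df = pd.read_csv(path, sep="\t").fillna("")
    required = {"component", "gene_id", "substructure", "synonyms"}
    if not required.issubset(df.columns):
        raise ValueError(f"component list needs columns {sorted(required)}")
    return df


def _synonym_index(components: pd.DataFrame) -> dict[str, str]:
    idx: dict[str, str] = {}
    for _, row in components.iterrows():
        keys = [row["component"], row["gene_id"]] + [
            s for s in str(row["synonyms"]).split("|") if s
        ]
        for k in keys:
            k = str(k).strip().lower()
            if k:
                idx[k] = row["component"]
    return idx


def map_components(
    results: pd.DataFrame, components: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Join enrichment results onto a component list by ID or synonym.

    Returns (component table, unassigned protein IDs).  Components
    absent from the results are reported with status "undetected" (grey
    in an increment colour scheme); result rows matching no component
    are listed as unassigned.
    """
    components = components if components is not None else load_components()
    syn = _synonym_index(components)
    assigned: dict[str, str] = {}
    unassigned: list[str] = []
    for pid in results.index:
        comp = syn.get(str(pid).strip().lower())
        if comp is None:
            unassigned.append(pid)
        elif comp not in assigned:
            assigned[comp] = pid
    rows = []
    for _, crow in components.iterrows():
        comp = crow["component"]
        if comp in assigned:
            r = results.loc[assigned[comp]]
            rows.append(
                {
                    "component": comp,
                    "substructure": crow["substructure"],
                    "protein_group": assigned[comp],
                    "status": "detected",
                    "t_test_difference": r["t_test_difference"],
                    "p_value": r["p_value"],
                    "increment_class": r.get("increment_class", np.nan),
                }
            )
        else:
            rows.append(
                {
                    "component": comp,
                    "substructure": crow["substructure"],
                    "protein_group": "",
                    "status": "undetected",
                    "t_test_difference": np.nan,
                    "p_value": np.nan,
                    "increment_class": np.nan,
                }
            )
    return pd.DataFrame(rows), unassigned


# --------------------------------------------------------------------------

def run_enrichment(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    bait_group: str,
    control_group: str,
    *,
    min_valid: int = 1,
    impute_params: ImputeParams = ImputeParams(),
    edges: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0),
    test: str = "student",
) -> pd.DataFrame:
    """Full pipeline: filter -> log2 -> impute -> t-test -> increments."""
    filtered, _removed = filter_valid(table, groups, bait_group, min_valid=min_valid)
    logged = log2_transform(filtered)
    imputed = impute(logged, impute_params)
    results = ttest_vs_control(imputed, groups, bait_group, control_group, test=test)
    return bin_increments(results, edges=edges)
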