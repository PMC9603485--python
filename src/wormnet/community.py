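"""OTU-table data model, I/O, rarefaction, alpha diversity, and shared-OTU partitions.

The table is the substrate of every downstream stage: rows are operational
taxonomic units (OTUs, 16S clusters at fixed similarity), columns are samples,
cells are read counts.  Taxonomy travels with the table as a 7-rank
semicolon-delimited lineage (kingdom;phylum;class;order;family;genus;species).
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_TAXONOMY_RANKS = 7

HABITATS = ("soil", "gut")
TREATMENTS = ("HM", "HML")
#: habitat suffix used in the 4 study group labels (soil -> "s", gut -> "e")
_HABITAT_SUFFIX = {"soil": "s", "gut": "e"}
GROUP_LABELS = ("HMs", "HMe", "HMLs", "HMLe")
ENV_COLUMNS = ("pH", "OM", "TN", "TP", "TK", "MC")


class OtuTableError(ValueError):
    """Raised when an OTU table violates its contract (parse or validation)."""


def normalize_lineage(lineage: str | None) -> str:
    """Pad/trim a semicolon-delimited lineage to exactly 7 ranks.

    Empty or missing taxonomy becomes 7 empty fields.  Whitespace around rank
    names is stripped; extra ranks beyond species are dropped.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        parts: list[str] = []
    else:
        parts = [p.strip() for p in str(lineage).split(";")]
        if parts == [""]:
            parts = []
    parts = parts[:N_TAXONOMY_RANKS]
    parts += [""] * (N_TAXONOMY_RANKS - len(parts))
    return ";".join(parts)


@dataclass
class OtuTable:
    """Counts matrix (rows = OTUs, cols = samples) with lineages.

    Invariants enforced at construction: integer counts >= 0, unique row and
    column identifiers, label lengths matching the matrix, 7-rank lineages.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (OTUs x samples)")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=0, rtol=0):
                raise OtuTableError("counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise OtuTableError(
                f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        if len(self.otu_ids) != self.counts.shape[0]:
            raise OtuTableError("number of otu_ids does not match count rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise OtuTableError("number of sample_ids does not match count columns")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise OtuTableError("duplicate otu_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OtuTableError("duplicate sample_ids")
        if not self.lineages:
            self.lineages = [""] * len(self.otu_ids)
        if len(self.lineages) != len(self.otu_ids):
            raise OtuTableError("number of lineages does not match otu_ids")
        self.lineages = [normalize_lineage(lin) for lin in self.lineages]

    # -- basic views ---------------------------------------------------------

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Total counts (sequencing depth) per sample."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="depth")

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1; all-zero columns stay 0)."""
        depths = self.counts.sum(axis=0).astype(float)
        depths[depths == 0] = 1.0
        return pd.DataFrame(
            self.counts / depths, index=self.otu_ids, columns=self.sample_ids
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            otu_ids=list(self.otu_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            counts=self.counts[:, idx].copy(),
            lineages=list(self.lineages),
        )

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return OtuTable(
            otu_ids=[self.otu_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :].copy(),
            lineages=[self.lineages[i] for i in idx],
        )

    def lineage_of(self, otu_id: str) -> str:
        return self.lineages[self.otu_ids.index(otu_id)]


# -- I/O ---------------------------------------------------------------------

OTU_ID_COLUMN = "#OTU_ID"
TAXONOMY_COLUMN = "taxonomy"


def read_otu_table(path) -> OtuTable:
    """Read a tab-separated OTU table.

    Layout: header row of sample IDs, first column ``#OTU_ID``, optional final
    ``taxonomy`` column with semicolon-delimited lineages (padded to 7 ranks).
    Non-integer or negative cells raise an error naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise OtuTableError(f"{path}: expected at least an OTU id and one sample column")
    otu_ids = df.iloc[:, 0].tolist()
    has_tax = df.columns[-1].strip().lower() == TAXONOMY_COLUMN
    sample_cols = list(df.columns[1:-1] if has_tax else df.columns[1:])
    lineages = df.iloc[:, -1].tolist() if has_tax else []
    counts = np.empty((len(otu_ids), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise OtuTableError(
                    f"{path}: non-integer count {raw!r} at OTU {otu_ids[i]!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise OtuTableError(
                    f"{path}: negative count {raw!r} at OTU {otu_ids[i]!r}, sample {col!r}"
                )
            counts[i, j] = value
    return OtuTable(otu_ids=otu_ids, sample_ids=sample_cols, counts=counts, lineages=lineages)


def write_otu_table(table: OtuTable, path) -> None:
    """Write the tab-separated layout that :func:`read_otu_table` consumes."""
    df = table.to_dataframe().copy()
    df.insert(0, OTU_ID_COLUMN, table.otu_ids)
    df[TAXONOMY_COLUMN] = table.lineages
    df.to_csv(path, sep="\t", index=False)


@dataclass
class SampleMetadata:
    """Per-sample design and environmental covariates.

    ``group_label`` is derived purely from (habitat, treatment): treatment name
    plus the habitat suffix ("s" for soil, "e" for earthworm gut), giving the
    four study groups HMs / HMe / HMLs / HMLe.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        for col in ("habitat", "treatment"):
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        bad = set(df["habitat"]) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitat values: {sorted(bad)}")
        df["group_label"] = [
            group_label(h, t) for h, t in zip(df["habitat"], df["treatment"])
        ]
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dupes}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> dict[str, list[str]]:
        """Mapping group label -> sample ids, in metadata order."""
        out: dict[str, list[str]] = {}
        for sid, lab in self.df["group_label"].items():
            out.setdefault(lab, []).append(sid)
        return out

    def samples_in_group(self, label: str) -> list[str]:
        if label in self.groups:
            return self.groups[label]
        if label in HABITATS:  # habitat-level pooling ("soil" / "gut")
            return list(self.df.index[self.df["habitat"] == label])
        raise KeyError(f"unknown group label {label!r}")

    def env(self) -> pd.DataFrame:
        cols = [c for c in ENV_COLUMNS if c in self.df.columns]
        return self.df[cols].astype(float)


def group_label(habitat: str, treatment: str) -> str:
    if habitat not in _HABITAT_SUFFIX:
        raise ValueError(f"unknown habitat {habitat!r} (expected one of {HABITATS})")
    return f"{treatment}{_HABITAT_SUFFIX[habitat]}"


def read_metadata(path) -> SampleMetadata:
    """Read the metadata TSV (sample_id, habitat, treatment, pH, OM, TN, TP, TK, MC)."""
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.drop(columns=["group_label"]).to_csv(path, sep="\t", index_label="sample_id")


# -- rarefaction -------------------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample column to ``depth`` reads without replacement.

    Each column is one multivariate-hypergeometric draw, so column sums equal
    ``depth`` exactly and no count can exceed its original value.  The same
    seed yields the identical table.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.counts.sum(axis=0)
    short = [sid for sid, tot in zip(table.sample_ids, totals) if tot < depth]
    if short:
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: {short}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return OtuTable(
        otu_ids=list(table.otu_ids),
        sample_ids=list(table.sample_ids),
        counts=out,
        lineages=list(table.lineages),
    )


# -- alpha diversity ---------------------------------------------------------


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Shannon H (nats), Chao1, richness S_obs and Pielou evenness per sample.

    H = -sum p_i ln p_i over nonzero proportions; J = H / ln(S_obs), undefined
    (NaN) for single-taxon samples; Chao1 is the classic estimator
    S_obs + F1^2/(2 F2), falling back to S_obs + F1(F1-1)/2 when F2 = 0.
    Warns when sample depths are unequal (indices are depth-sensitive; rarefy
    first).
    """
    depths = table.counts.sum(axis=0)
    if (depths == 0).any():
        zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"all-zero samples: {zero}")
    if len(set(depths.tolist())) > 1:
        warnings.warn(
            "sample depths are unequal; alpha diversity is depth-sensitive "
            "(rarefy to a common depth first)",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        h = _shannon(col)
        s_obs = int((col > 0).sum())
        j_even = h / np.log(s_obs) if s_obs > 1 else np.nan
        rows.append(
            {"sample_id": sid, "shannon": h, "chao1": _chao1(col),
             "richness": s_obs, "evenness": j_even}
        )
    return pd.DataFrame(rows).set_index("sample_id")


# -- shared / unique OTU partitions ------------------------------------------


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention behind reported percentages)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class VennPartition:
    """Shared / unique OTU sets for a pair of sample groups."""

    group_a: str
    group_b: str
    shared: frozenset
    unique_a: frozenset
    unique_b: frozenset

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.unique_a) + len(self.unique_b)

    @property
    def shared_pct(self) -> float:
        """Full-precision shared percentage of the union."""
        if self.union_size == 0:
            return 0.0
        return 100.0 * len(self.shared) / self.union_size

    @property
    def shared_pct_reported(self) -> float:
        """Shared percentage rounded half-up to 1 decimal, as reported."""
        return round_half_up(self.shared_pct, 1)


def venn_partition(
    table: OtuTable, meta: SampleMetadata, group_a: str, group_b: str
) -> VennPartition:
    """Partition OTUs into shared / unique-to-A / unique-to-B between two groups.

    An OTU belongs to a group when its summed count over the group's samples is
    positive (presence in any replicate).
    """
    df = table.to_dataframe()
    sets = []
    for label in (group_a, group_b):
        samples = meta.samples_in_group(label)
        present = df[samples].sum(axis=1) > 0
        sets.append(frozenset(df.index[present]))
    a, b = sets
    return VennPartition(
        group_a=group_a,
        group_b=group_b,
        shared=a & b,
        unique_a=a - b,
        unique_b=b - a,
    )


def depth_report(table: OtuTable, meta: SampleMetadata) -> pd.DataFrame:
    """Sequencing-depth summary per habitat: total, n samples, mean (half-up int)."""
    depths = table.sample_depths()
    rows = []
    for habitat in HABITATS:
        samples = [s for s in table.sample_ids if meta.df.loc[s, "habitat"] == habitat]
        if not samples:
            continue
        total = int(depths[samples].sum())
        rows.append(
            {"habitat": habitat, "n_samples": len(samples), "total_reads": total,
             "mean_reads": round_half_up(total / len(samples), 0)}
        )
    return pd.DataFrame(rows).set_index("habitat")


# -- group comparison (ANOVA + Tukey HSD + compact letters) ------------------


@dataclass
class GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD and a compact-letter display."""

    anova_f: float
    anova_p: float
    group_means: pd.Series
    tukey: pd.DataFrame  # group1, group2, mean_diff, q, p_adj
    letters: dict[str, str]

    def summary(self) -> str:
        lines = [f"ANOVA: F = {self.anova_f:.4g}, p = {self.anova_p:.4g}", ""]
        for g, m in self.group_means.items():
            lines.append(f"  {g}: mean = {m:.4g}  [{self.letters[g]}]")
        return "\n".join(lines)


def _tukey_pairs(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    labels = list(groups)
    k = len(labels)
    n_total = sum(len(v) for v in groups.values())
    df_err = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[labels[i]], groups[labels[j]]
            diff = b.mean() - a.mean()
            # Tukey-Kramer standard error for unequal n
            se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_err))
            rows.append(
                {"group1": labels[i], "group2": labels[j],
                 "mean_diff": diff, "q": q, "p_adj": min(1.0, p)}
            )
    return pd.DataFrame(rows)


def _compact_letters(labels: Sequence[str], means: pd.Series, tukey: pd.DataFrame,
                     alpha: float) -> dict[str, str]:
    """Insert-and-absorb compact-letter display from pairwise p-values."""
    sig = {
        frozenset((r.group1, r.group2)): r.p_adj < alpha for r in tukey.itertuples()
    }
    order = list(means.sort_values(ascending=False).index)
    letter_sets: list[set[str]] = [set(order)]  # start optimistic: one group
    for a_i in range(len(order)):
        for b_i in range(a_i + 1, len(order)):
            a, b = order[a_i], order[b_i]
            if not sig.get(frozenset((a, b)), False):
                continue
            new_sets = []
            for s in letter_sets:
                if a in s and b in s:
                    new_sets.extend([s - {b}, s - {a}])
                else:
                    new_sets.append(s)
            # absorb duplicates/subsets
            letter_sets = []
            for s in sorted(new_sets, key=len, reverse=True):
                if not any(s <= t for t in letter_sets):
                    letter_sets.append(s)
    # stable letter assignment: order sets by the highest-mean member
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in labels}
    for idx, s in enumerate(letter_sets):
        ch = chr(ord("a") + idx)
        for g in s:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in labels}


def group_compare(values: pd.Series, meta: SampleMetadata, alpha: float = 0.05,
                  by: str = "group_label") -> GroupComparison:
    """Compare a per-sample quantity across groups (ANOVA + Tukey HSD letters).

    Requires >= 2 groups with >= 2 samples each.  All-identical data is
    reported as "no difference" (F = 0, p = 1, one shared letter).
    """
    values = values.astype(float)
    grouping = meta.df.loc[values.index, by]
    groups = {str(g): values[grouping == g].to_numpy() for g in grouping.unique()}
    if len(groups) < 2:
        raise ValueError("group_compare needs at least 2 groups")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    means = pd.Series({g: v.mean() for g, v in groups.items()})
    if np.ptp(values.to_numpy()) == 0:
        labels = list(groups)
        tukey = _tukey_pairs(groups)
        return GroupComparison(0.0, 1.0, means, tukey, {g: "a" for g in labels})
    f, p = stats.f_oneway(*groups.values())
    if np.isnan(f):  # zero within-group variance with equal means
        f, p = 0.0, 1.0
    tukey = _tukey_pairs(groups)
    letters = _compact_letters(list(groups), means, tukey, alpha)
    return GroupComparison(float(f), float(p), means, tukey, letters)


def presence_fraction(table: OtuTable) -> pd.Series:
    """Fraction of samples in which each OTU is present (count > 0)."""
    frac = (table.counts > 0).mean(axis=1)
    return pd.Series(frac, index=table.otu_ids, name="prevalence")


def as_fraction(value) -> Fraction:
    """Exact fraction for threshold comparisons (2/3 stays 2/3, not a float)."""
    if isinstance(value, Fraction):
        return value
    return Fraction(value).limit_denominator(10**6)
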