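"""Assembly of the multimodal feature table and the cohort statistics.

Three modalities enter the classification stage:

* GM — taxa abundances after the prevalence filter (a taxon missing, i.e.
  zero, in more than 85% of participants is removed);
* Blood — the 12-feature panel, with the inflammation indices
  NLR = NEU/LYM, PLR = PLT/LYM, MLR = MON/LYM and the systemic
  immune-inflammation index SIII = PLT * NEU / LYM recomputed from counts;
* EEG — network AUC features after a completeness filter that removes any
  feature missing for at least one participant.

The modalities are used individually or concatenated ("Combined") to form
the four input feature sets.  Demographic group comparisons use a Welch
two-sample t test (age, education) and a Pearson chi-square test without
continuity correction (sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "MODALITIES",
    "INPUT_SETS",
    "blood_indices",
    "prevalence_filter",
    "completeness_filter",
    "assemble",
    "summary_t_test",
    "chi_square_2x2",
    "cohort_statistics",
]

MODALITIES: tuple[str, ...] = ("GM", "Blood", "EEG")
INPUT_SETS: tuple[str, ...] = ("GM", "Blood", "EEG", "Combined")


@dataclass
class FeatureTable:
    """Subjects x named features with per-feature modality tags.

    data : DataFrame indexed by subject_id.
    modality : feature name -> 'GM' | 'Blood' | 'EEG'.
    groups : subject_id -> 'SZ' | 'HC', aligned with ``data.index``.
    """

    data: pd.DataFrame
    modality: dict[str, str]
    groups: pd.Series

    def __post_init__(self) -> None:
        if set(self.data.columns) != set(self.modality):
            raise ValueError("modality tags must cover exactly the feature columns")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ValueError("group label missing for some subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def labels(self) -> np.ndarray:
        """Binary labels with SZ as the positive class."""
        return (self.groups == "SZ").to_numpy().astype(int)

    def subset(self, subjects: pd.Index | np.ndarray) -> "FeatureTable":
        return FeatureTable(self.data.loc[subjects], dict(self.modality),
                            self.groups.loc[subjects])

    def select_columns(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.data[columns],
                            {c: self.modality[c] for c in columns}, self.groups)


def blood_indices(WBC, NEU, LYM, PLT, MON):
    """Inflammation indices from the five cell counts.

    NLR = NEU/LYM, PLR = PLT/LYM, MLR = MON/LYM,
    SIII = PLT * NEU / LYM (the standard systemic immune-inflammation
    index definition).  WBC is accepted for signature completeness but does
    not enter any index.  Requires LYM > 0.
    """
    LYM = np.asarray(LYM, dtype=float)
    if np.any(LYM <= 0):
        raise ValueError("lymphocyte count must be positive")
    NEU = np.asarray(NEU, dtype=float)
    PLT = np.asarray(PLT, dtype=float)
    MON = np.asarray(MON, dtype=float)
    return NEU / LYM, PLT / LYM, MON / LYM, PLT * NEU / LYM


def prevalence_filter(taxa: pd.DataFrame, missing_frac: float = 0.85) -> pd.DataFrame:
    """Remove taxa missing (zero) in more than ``missing_frac`` of subjects.

    A taxon is retained iff its fraction of zero-abundance subjects is at
    most ``missing_frac`` (strictly-greater-than removal).  Column order is
    preserved; the operation is idempotent.
    """
    if not 0 < missing_frac < 1:
        raise ValueError("missing_frac must be in (0, 1)")
    if taxa.shape[0] == 0 or taxa.shape[1] == 0:
        return taxa.copy()
    if (taxa.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_frac = (taxa == 0).mean(axis=0)
    return taxa.loc[:, zero_frac <= missing_frac].copy()


def completeness_filter(ft: FeatureTable, scope: str = "EEG") -> FeatureTable:
    """Drop, within one modality, every feature missing for any participant.

    Other modalities are untouched; column order is preserved.
    """
    if scope not in MODALITIES:
        raise ValueError(f"scope must be one of {MODALITIES}")
    keep = [
        c for c in ft.data.columns
        if ft.modality[c] != scope or not ft.data[c].isna().any()
    ]
    return ft.select_columns(keep)


def assemble(
    gm: pd.DataFrame | None,
    blood: pd.DataFrame | None,
    eeg: pd.DataFrame | None,
    groups: pd.Series,
    mode: str = "Combined",
    apply_filters: bool = True,
    missing_frac: float = 0.85,
) -> FeatureTable:
    """Build one of the four input feature sets.

    ``mode`` selects GM, Blood, EEG or Combined (column-wise concatenation of
    all three).  With ``apply_filters`` the GM table passes the prevalence
    filter and the EEG table the completeness filter first.  All supplied
    modalities must cover the same subject set.
    """
    if mode not in INPUT_SETS:
        raise ValueError(f"mode must be one of {INPUT_SETS}")
    wanted = MODALITIES if mode == "Combined" else (mode,)
    supplied = {"GM": gm, "Blood": blood, "EEG": eeg}
    parts: list[pd.DataFrame] = []
    tags: dict[str, str] = {}
    ref_index: pd.Index | None = None
    for tag in wanted:
        df = supplied[tag]
        if df is None:
            raise ValueError(f"mode {mode!r} requires the {tag} table")
        if ref_index is None:
            ref_index = df.index
        elif not ref_index.equals(df.index):
            offenders = ref_index.symmetric_difference(df.index).tolist()
            raise ValueError(f"subject sets differ across modalities: {offenders}")
        if tag == "GM" and apply_filters:
            df = prevalence_filter(df, missing_frac)
        parts.append(df)
        tags.update({c: tag for c in df.columns})
    data = pd.concat(parts, axis=1)
    ft = FeatureTable(data=data, modality=tags, groups=groups)
    if apply_filters and "EEG" in wanted:
        ft = completeness_filter(ft, scope="EEG")
    return ft


def summary_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t test from summary statistics.

    Returns (t, two-tailed p) with Welch-Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) of a 2x2 table
    [[a, b], [c, d]]; p from chi-square with 1 df."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all margins must be positive")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cohort_statistics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison table for the cohort demographics.

    Welch t for age and education; Pearson chi-square for the sex
    distribution (its signed square root is also reported, since a 2x2
    chi-square is the square of the two-proportion z statistic).
    """
    sz = cohort[cohort["group"] == "SZ"]
    hc = cohort[cohort["group"] == "HC"]
    rows = []
    for col in ("age", "education"):
        t, p = summary_t_test(
            sz[col].mean(), sz[col].std(ddof=1), len(sz),
            hc[col].mean(), hc[col].std(ddof=1), len(hc),
        )
        rows.append((col, "welch_t", t, p))
    a = int((sz["sex"] == "M").sum())
    b = int((sz["sex"] == "F").sum())
    c = int((hc["sex"] == "M").sum())
    d = int((hc["sex"] == "F").sum())
    stat, p = chi_square_2x2(a, b, c, d)
    rows.append(("sex", "chi2", stat, p))
    rows.append(("sex", "sqrt_chi2", float(np.sign(a * d - b * c) * np.sqrt(stat)), p))
    return pd.DataFrame(rows, columns=["characteristic", "statistic", "value", "p"])
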