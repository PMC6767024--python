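"""Volatile quantification and heterosis indices.

GC-MS peak areas are converted to concentrations against a single internal
standard (ethyl decanoate by default: 15 uL of a 100 ppm solution = 1.5 ug
spiked into the extraction).  Compound classes (green leaf volatiles,
monoterpenes, sesquiterpenes) are summed per genotype, and hybrid vigour is
expressed as

    MPV (%) = (F1 - MP) / MP * 100,   MP = (parent1 + parent2) / 2
    OPV (%) = (F1 - HP) / HP * 100,   HP = max(parent1, parent2)

MPV is mid-parent heterosis; OPV (also written HPV) is over-high-parent
heterosis.  Group differences are summarised as a compact letter display
from pairwise Welch t-tests.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COMPOUND_CLASSES = ("GLV", "monoterpene", "sesquiterpene")

#: 15 uL x 100 ppm internal-standard spike, in micrograms
DEFAULT_IS_MASS_UG = 1.5


# ---------------------------------------------------------------------------
# internal-standard semi-quantification
# ---------------------------------------------------------------------------

def quantify_internal_standard(
    target_area: float,
    is_area: float,
    is_mass_ug: float = DEFAULT_IS_MASS_UG,
    sample_mass_g: float = 5.0,
) -> float:
    """Concentration of a target compound in ng/g of sample.

    The target peak area is scaled by the known internal-standard mass:
    ``(target_area / is_area) * is_mass_ug * 1000 / sample_mass_g``.
    """
    if is_area <= 0:
        raise ZeroDivisionError(
            "internal-standard peak area must be positive (got "
            f"{is_area!r}); cannot form the area ratio"
        )
    if sample_mass_g <= 0:
        raise ZeroDivisionError(
            f"sample mass must be positive (got {sample_mass_g!r})"
        )
    if target_area < 0:
        raise ValueError("negative target peak area")
    return (target_area / is_area) * is_mass_ug * 1000.0 / sample_mass_g


# ---------------------------------------------------------------------------
# volatile table
# ---------------------------------------------------------------------------

@dataclass
class VolatileTable:
    """Long-format compound concentrations.

    ``data`` columns: compound, compound_class, genotype, replicate,
    concentration (ng/g).  Every compound must appear for all genotypes
    present in the table and carry a single class label.
    """

    data: pd.DataFrame

    REQUIRED = ("compound", "compound_class", "genotype", "replicate", "concentration")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"volatile table missing columns: {sorted(missing)}")
        if (self.data["concentration"] < 0).any():
            raise ValueError("negative concentration")
        per_compound = self.data.groupby("compound")["compound_class"].nunique()
        bad = per_compound[per_compound > 1]
        if len(bad):
            raise ValueError(
                f"compound(s) with inconsistent class labels: {list(bad.index)}"
            )
        genotypes = set(self.data["genotype"].unique())
        cover = self.data.groupby("compound")["genotype"].agg(set)
        incomplete = cover[cover != genotypes]
        if len(incomplete):
            raise ValueError(
                "compound(s) missing one or more genotypes: "
                f"{list(incomplete.index)}"
            )

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    def compound_means(self) -> pd.DataFrame:
        """Mean concentration per (compound, genotype), class label carried."""
        return (
            self.data.groupby(["compound", "compound_class", "genotype"])[
                "concentration"
            ]
            .mean()
            .reset_index()
        )

    def replicate_values(self, compound: str, genotype: str) -> np.ndarray:
        sel = (self.data["compound"] == compound) & (self.data["genotype"] == genotype)
        return self.data.loc[sel, "concentration"].to_numpy(dtype=float)


def class_sum(table: VolatileTable, compound_class: str, genotype: str) -> float:
    """Total concentration of a compound class for one genotype.

    Sum of per-compound mean concentrations — the "Sum" row of a volatile
    content table.  An empty class returns 0 with a warning.
    """
    means = table.compound_means()
    sel = (means["compound_class"] == compound_class) & (
        means["genotype"] == genotype
    )
    if not sel.any():
        warnings.warn(
            f"no compounds of class {compound_class!r} for genotype "
            f"{genotype!r}; class sum is 0",
            stacklevel=2,
        )
        return 0.0
    return float(means.loc[sel, "concentration"].sum())


def class_sum_replicates(
    table: VolatileTable, compound_class: str, genotype: str
) -> np.ndarray:
    """Per-replicate class totals (for letter-group testing on sums)."""
    sel = (table.data["compound_class"] == compound_class) & (
        table.data["genotype"] == genotype
    )
    sub = table.data.loc[sel]
    if sub.empty:
        return np.zeros(0)
    return sub.groupby("replicate")["concentration"].sum().to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# heterosis indices
# ---------------------------------------------------------------------------

@dataclass
class HeterosisResult:
    trait_id: str
    f1: float
    mp: float
    hp: float
    mpv: float
    opv: float


def mid_parent_heterosis(f1: float, p1: float, p2: float) -> float:
    """MPV (%) = (F1 - MP)/MP * 100 with MP the mid-parent mean."""
    mp = (p1 + p2) / 2.0
    if mp == 0:
        raise ZeroDivisionError("mid-parent mean is zero; MPV undefined")
    return (f1 - mp) / mp * 100.0


def over_high_parent_heterosis(f1: float, p1: float, p2: float) -> float:
    """OPV (%) = (F1 - HP)/HP * 100 with HP the high-value parent."""
    hp = max(p1, p2)
    if hp == 0:
        raise ZeroDivisionError("high-parent value is zero; OPV undefined")
    return (f1 - hp) / hp * 100.0


def heterosis(trait_id: str, f1: float, p1: float, p2: float) -> HeterosisResult:
    """Both heterosis indices for one trait."""
    return HeterosisResult(
        trait_id=trait_id,
        f1=f1,
        mp=(p1 + p2) / 2.0,
        hp=max(p1, p2),
        mpv=mid_parent_heterosis(f1, p1, p2),
        opv=over_high_parent_heterosis(f1, p1, p2),
    )


def heterosis_table(
    table: VolatileTable,
    hybrids: Sequence[str],
    parents: Sequence[str],
) -> pd.DataFrame:
    """Class-level MPV/OPV for each hybrid, from class sums of means."""
    if len(parents) != 2:
        raise ValueError("exactly two parents required")
    rows = []
    classes = [
        c for c in COMPOUND_CLASSES if c in set(table.data["compound_class"])
    ]
    for hybrid in hybrids:
        for cls in classes:
            f1 = class_sum(table, cls, hybrid)
            p1 = class_sum(table, cls, parents[0])
            p2 = class_sum(table, cls, parents[1])
            res = heterosis(f"{hybrid}:{cls}", f1, p1, p2)
            rows.append(
                {
                    "hybrid": hybrid,
                    "compound_class": cls,
                    "F1": res.f1,
                    "MP": res.mp,
                    "HP": res.hp,
                    "MPV_percent": res.mpv,
                    "OPV_percent": res.opv,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------

def _pairwise_welch_p(groups: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    p: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            p[(a, b)] = 0.0 if not np.isclose(xa.mean(), xb.mean()) else 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pv = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            p[(a, b)] = 1.0 if np.isnan(pv) else pv
    return p


def letters_from_pmatrix(
    p: Mapping[tuple[str, str], float],
    means: Mapping[str, float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise p-value map.

    Letters are assigned in order of decreasing group mean, so the group
    with the highest mean always carries "a".
    """
    names = sorted(means, key=lambda g: (-means[g], g))
    pmat = dict(p)
    pmat.update({(b, a): v for (a, b), v in p.items()})
    # start with a single letter set containing every group
    letter_sets: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if pmat[(a, b)] >= alpha:
            continue
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb sets contained in another
        letter_sets = [
            s
            for s in new_sets
            if s and not any(s < t for t in new_sets if t is not s)
        ]
        # drop duplicates
        uniq: list[set[str]] = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    # order letter sets by the best (highest-mean) member they contain
    rank = {g: i for i, g in enumerate(names)}
    letter_sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = string.ascii_lowercase
    out = {g: "" for g in names}
    for i, s in enumerate(letter_sets):
        ch = alphabet[i % len(alphabet)]
        for g in names:
            if g in s:
                out[g] += ch
    return out


def letter_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> dict[str, str]:
    """Compact letter display over replicate groups via pairwise Welch tests.

    Groups sharing a letter are not significantly different at ``alpha``;
    raw p-values by default (set ``bonferroni`` to correct for the number
    of pairs).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    p = _pairwise_welch_p(groups)
    if bonferroni:
        m = len(p)
        p = {k: min(1.0, v * m) for k, v in p.items()}
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    return letters_from_pmatrix(p, means, alpha=alpha)


def summary_table(table: VolatileTable, alpha: float = 0.05) -> pd.DataFrame:
    """Mean +/- SD with significance letters per compound, plus class sums."""
    rows = []
    genotypes = table.genotypes
    for (compound, cls), sub in table.data.groupby(
        ["compound", "compound_class"], sort=False
    ):
        groups = {
            g: sub.loc[sub["genotype"] == g, "concentration"].to_numpy()
            for g in genotypes
        }
        letters = letter_groups(groups, alpha=alpha)
        row: dict[str, object] = {"compound": compound, "compound_class": cls}
        for g in genotypes:
            row[f"{g}_mean"] = float(np.mean(groups[g]))
            row[f"{g}_sd"] = float(np.std(groups[g], ddof=1))
            row[f"{g}_letter"] = letters[g]
        rows.append(row)
    for cls in COMPOUND_CLASSES:
        if cls not in set(table.data["compound_class"]):
            continue
        groups = {g: class_sum_replicates(table, cls, g) for g in genotypes}
        if any(len(v) < 2 for v in groups.values()):
            continue
        letters = letter_groups(groups, alpha=alpha)
        row = {"compound": f"Sum ({cls})", "compound_class": cls}
        for g in genotypes:
            row[f"{g}_mean"] = class_sum(table, cls, g)
            row[f"{g}_sd"] = float(np.std(groups[g], ddof=1))
            row[f"{g}_letter"] = letters[g]
        rows.append(row)
    return pd.DataFrame(rows)
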