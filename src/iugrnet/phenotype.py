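"""Littermate-based growth classification and discordant sib-pair selection.

Intrauterine growth restriction (IUGR) is defined relative to the litter: a
fetus is IUGR when its weight falls more than ``sd_multiplier`` (default 2)
sample standard deviations below the mean weight of its littermates.  The
littermate mean/SD exclude the index fetus itself, so a single extreme runt
cannot inflate its own threshold.  Normally grown littermates are AGA
(appropriate for gestational age).

From the labeled litters, sex-matched discordant (IUGR, AGA) sib pairs are
selected per dam, maximizing the within-pair weight difference, giving the
balanced two-group cohort used by all downstream expression analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

IUGR = "IUGR"
AGA = "AGA"
UNASSIGNED = "unassigned"

__all__ = [
    "FetusRecord",
    "GroupSummary",
    "PairSelectionError",
    "classify_iugr",
    "select_discordant_pairs",
    "summarize_groups",
    "fetuses_to_frame",
    "frame_to_fetuses",
    "load_example_cohort",
]


@dataclass(frozen=True)
class FetusRecord:
    """One fetus: the unit of the discordant sib-pair design."""

    fetus_id: str
    dam: str
    sex: str  # "male" | "female"
    weight: float  # grams
    group: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"fetus {self.fetus_id}: weight must be > 0 g")
        if not self.dam:
            raise ValueError(f"fetus {self.fetus_id}: dam must be non-empty")
        if self.sex not in ("male", "female"):
            raise ValueError(f"fetus {self.fetus_id}: sex must be male/female")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_weight: float
    sd_weight: float
    sem_weight: float


class PairSelectionError(ValueError):
    """Raised when fewer discordant pairs are attainable than requested."""


def classify_iugr(fetuses, sd_multiplier: float = 2.0):
    """Label each fetus IUGR or AGA by the littermate 2-SD rule.

    A fetus is IUGR iff ``weight < mean(littermates) - sd_multiplier * SD(littermates)``
    (strict inequality), where littermates exclude the index fetus.  Litters
    with fewer than 4 fetuses are skipped with a warning (the littermate SD
    is too unstable) and left unassigned.
    """
    fetuses = list(fetuses)
    by_dam: dict[str, list[FetusRecord]] = {}
    for f in fetuses:
        by_dam.setdefault(f.dam, []).append(f)

    out = []
    for f in fetuses:
        litter = by_dam[f.dam]
        if len(litter) < 4:
            out.append(replace(f, group=UNASSIGNED))
            continue
        others = np.array([g.weight for g in litter if g.fetus_id != f.fetus_id])
        threshold = others.mean() - sd_multiplier * others.std(ddof=1)
        out.append(replace(f, group=IUGR if f.weight < threshold else AGA))

    small = sorted({d for d, lit in by_dam.items() if len(lit) < 4})
    if small:
        warnings.warn(
            f"litters with < 4 fetuses skipped (SD unstable): {', '.join(small)}",
            stacklevel=2,
        )
    return out


def select_discordant_pairs(fetuses, n_per_group: int = 12):
    """Select sex-matched discordant (IUGR, AGA) littermate pairs.

    Within each litter, IUGR fetuses (lightest first) are matched to the
    heaviest available AGA littermate of the same sex.  Candidate pairs are
    then ranked globally by within-pair weight difference (descending; ties
    broken by lexicographic fetus_id) and the top ``n_per_group`` pairs kept.

    Returns ``(selected, pairs)`` where ``selected`` is the flat list of the
    2 * n_per_group chosen fetuses and ``pairs`` the list of
    ``(iugr_record, aga_record)`` tuples.
    """
    by_dam: dict[str, list[FetusRecord]] = {}
    for f in fetuses:
        by_dam.setdefault(f.dam, []).append(f)

    candidates = []
    for dam in sorted(by_dam):
        litter = by_dam[dam]
        iugr = sorted(
            (f for f in litter if f.group == IUGR),
            key=lambda f: (f.weight, f.fetus_id),
        )
        avail = {
            sex: sorted(
                (f for f in litter if f.group == AGA and f.sex == sex),
                key=lambda f: (-f.weight, f.fetus_id),
            )
            for sex in ("male", "female")
        }
        for runt in iugr:
            pool = avail[runt.sex]
            if not pool:
                continue  # no same-sex AGA littermate left: contributes no pair
            partner = pool.pop(0)
            candidates.append((runt, partner))

    candidates.sort(
        key=lambda p: (-(p[1].weight - p[0].weight), p[0].fetus_id, p[1].fetus_id)
    )
    if len(candidates) < n_per_group:
        raise PairSelectionError(
            f"only {len(candidates)} sex-matched discordant pairs attainable, "
            f"{n_per_group} requested (deficit {n_per_group - len(candidates)})"
        )
    pairs = candidates[:n_per_group]
    selected = [f for pair in pairs for f in pair]
    return selected, pairs


def summarize_groups(fetuses):
    """Per-group weight summaries plus a Welch test for the group contrast.

    Returns ``(summary_frame, welch_p)``.  SD uses the n-1 denominator and
    SEM = SD / sqrt(n).
    """
    weights: dict[str, list[float]] = {}
    for f in fetuses:
        if f.group in (IUGR, AGA):
            weights.setdefault(f.group, []).append(f.weight)
    if not weights:
        raise ValueError("no fetuses with assigned groups")
    rows = []
    for group in (AGA, IUGR):
        w = np.asarray(weights.get(group, []), dtype=float)
        if w.size < 2:
            raise ValueError(f"group {group} has fewer than 2 fetuses")
        sd = float(w.std(ddof=1))
        rows.append(
            GroupSummary(group, int(w.size), float(w.mean()), sd, sd / np.sqrt(w.size))
        )
    welch_p = float(
        stats.ttest_ind(weights[AGA], weights[IUGR], equal_var=False).pvalue
    )
    frame = pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "mean_weight_g": s.mean_weight,
                "sd_weight_g": s.sd_weight,
                "sem_weight_g": s.sem_weight,
                "welch_p": welch_p,
            }
            for s in rows
        ]
    )
    return frame, welch_p


def fetuses_to_frame(fetuses) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fetus_id": f.fetus_id,
                "dam": f.dam,
                "sex": f.sex,
                "weight_g": f.weight,
                "group": f.group,
            }
            for f in fetuses
        ]
    )


def frame_to_fetuses(frame: pd.DataFrame):
    return [
        FetusRecord(
            fetus_id=str(r.fetus_id),
            dam=str(r.dam),
            sex=str(r.sex),
            weight=float(r.weight_g),
            group=str(getattr(r, "group", UNASSIGNED)),
        )
        for r in frame.itertuples(index=False)
    ]


def load_example_cohort():
    """The packaged 24-fetus discordant sib-pair cohort (one sire, 8 dams, 63 dpc)."""
    with resources.files("iugrnet.data").joinpath("pig_f2_cohort.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return frame_to_fetuses(frame)
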