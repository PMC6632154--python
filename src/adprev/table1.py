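"""Seeded person-level fixture reproducing the study's published cohort bookkeeping.

The study tables report, for each clinical group (cognitively unimpaired, MCI,
dementia actively enrolled, dementia passively ascertained), the group size,
sex counts, education-category counts, and APOE e4 carrier counts — separately
for the clinical cohort and for the nested amyloid PET and tau PET subcohorts.
Because the subcohorts are nested, each clinical group is decomposed here into
three disjoint blocks:

* ``tau``      — in all three cohorts,
* ``amy_only`` — amyloid PET but no tau PET,
* ``clin_only``— clinical cohort only,

and each block carries the *difference* of the printed cohort-level counts, so
that every printed marginal cell is reproduced exactly by construction.  The
enrollment-flow frame (nonparticipants, administrative exclusions,
unclassifiable participants) is appended so that the screening flowchart
counts are reproduced as well.

Ages are drawn uniformly within each block's printed interquartile range
(clipped to the printed range); SUVR values and the probable-AD share of
dementia are synthetic.  The fixture asserts counts, never distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import OPTIONAL_COLUMNS, REQUIRED_COLUMNS, TAU_COLUMNS

#: printed per-cohort, per-group cells (clinical / amyloid / tau cohorts).
#: education tuples are (<12, 12, 13-16, >16); denominators may be < n.
TABLE1 = {
    "clinical": {
        "CU": {"n": 3926, "women": 1989, "edu": (210, 1169, 1733, 809), "edu_n": 3921,
               "apoe": (2673, 955), "apoe_n": 3628},
        "MCI": {"n": 640, "women": 280, "edu": (96, 250, 211, 82), "edu_n": 639,
                "apoe": (390, 179), "apoe_n": 569},
        "dementia_active": {"n": 94, "women": 38, "edu": (30, 30, 24, 10), "edu_n": 94,
                            "apoe": (44, 39), "apoe_n": 83},
        "dementia_passive": {"n": 553, "women": 308, "edu": (125, 186, 170, 47), "edu_n": 528,
                             "apoe": None, "apoe_n": 0},
    },
    "amyloid": {
        "CU": {"n": 1241, "women": 585, "edu": (30, 321, 585, 305), "edu_n": 1241,
               "apoe": (896, 319), "apoe_n": 1215},
        "MCI": {"n": 241, "women": 99, "edu": (24, 84, 94, 38), "edu_n": 240,
                "apoe": (136, 88), "apoe_n": 224},
        "dementia_active": {"n": 42, "women": 14, "edu": (4, 19, 14, 5), "edu_n": 42,
                            "apoe": (19, 21), "apoe_n": 40},
    },
    "tau": {
        "CU": {"n": 490, "women": 227, "edu": (9, 119, 249, 113), "edu_n": 490,
               "apoe": (333, 132), "apoe_n": 465},
        "MCI": {"n": 70, "women": 33, "edu": (6, 24, 28, 11), "edu_n": 69,
                "apoe": (34, 19), "apoe_n": 53},
        "dementia_active": {"n": 16, "women": 6, "edu": (1, 6, 7, 2), "edu_n": 16,
                            "apoe": (6, 8), "apoe_n": 14},
    },
}

#: screening/enrollment flowchart counts
FIGURE1 = {
    "administrative_exclusions": 770,
    "unable_to_contact": 626,
    "terminal_illness": 100,
    "other_exclusions": 44,
    "nonparticipants": 5643,
    "died_after_contact": 40,
    "telephone_only": 1847,
    "refused": 3756,
    "passive_dementia": 553,
    "in_person_classified": 4660,
    "unclassifiable": 12,
    "clinical_cohort": 5213,
    "amyloid_cohort": 1524,
    "tau_cohort": 576,
}

_EDU_LEVELS = ["<12", "12", "13-16", ">16"]

# per-block ages: (median irrelevant, iqr lo, iqr hi, range lo, range hi)
_AGES = {
    ("CU", "tau"): (69, 83, 61, 98),
    ("CU", "amy_only"): (69, 82, 61, 98),
    ("CU", "clin_only"): (71, 81, 60, 91),
    ("MCI", "tau"): (74, 85, 62, 97),
    ("MCI", "amy_only"): (77, 87, 61, 97),
    ("MCI", "clin_only"): (74, 85, 60, 91),
    ("dementia_active", "tau"): (79, 88, 76, 90),
    ("dementia_active", "amy_only"): (81, 87, 72, 92),
    ("dementia_active", "clin_only"): (80, 87, 66, 91),
    ("dementia_passive", "all"): (80, 87, 61, 91),
}


def _block_counts() -> list[dict]:
    """Decompose printed cohort-level cells into disjoint nesting blocks."""

    def diff(a, b):
        return tuple(x - y for x, y in zip(a, b))

    blocks = []
    for group in ["CU", "MCI", "dementia_active"]:
        c, a, t = TABLE1["clinical"][group], TABLE1["amyloid"][group], TABLE1["tau"][group]
        spec = {
            "tau": {
                "n": t["n"], "women": t["women"], "edu": t["edu"],
                "edu_missing": t["n"] - t["edu_n"],
                "apoe": t["apoe"], "apoe_missing": t["n"] - t["apoe_n"],
            },
            "amy_only": {
                "n": a["n"] - t["n"], "women": a["women"] - t["women"],
                "edu": diff(a["edu"], t["edu"]),
                "edu_missing": (a["n"] - a["edu_n"]) - (t["n"] - t["edu_n"]),
                "apoe": diff(a["apoe"], t["apoe"]),
                "apoe_missing": (a["n"] - a["apoe_n"]) - (t["n"] - t["apoe_n"]),
            },
            "clin_only": {
                "n": c["n"] - a["n"], "women": c["women"] - a["women"],
                "edu": diff(c["edu"], a["edu"]),
                "edu_missing": (c["n"] - c["edu_n"]) - (a["n"] - a["edu_n"]),
                "apoe": diff(c["apoe"], a["apoe"]),
                "apoe_missing": (c["n"] - c["apoe_n"]) - (a["n"] - a["apoe_n"]),
            },
        }
        for name, b in spec.items():
            assert b["n"] >= 0 and b["women"] >= 0 and all(e >= 0 for e in b["edu"])
            blocks.append({"group": group, "block": name, **b})
    p = TABLE1["clinical"]["dementia_passive"]
    blocks.append({
        "group": "dementia_passive", "block": "all", "n": p["n"], "women": p["women"],
        "edu": p["edu"], "edu_missing": p["n"] - p["edu_n"], "apoe": None,
        "apoe_missing": p["n"],
    })
    return blocks


def _draw_ages(rng, n, key):
    lo, hi, rlo, rhi = _AGES[key]
    return np.clip(rng.integers(lo, hi + 1, size=n), rlo, rhi)


def _categorical_fill(counts_and_levels, n, rng):
    """Deterministically sized, randomly permuted categorical assignment."""
    vals = []
    for level, count in counts_and_levels:
        vals.extend([level] * count)
    assert len(vals) == n, (len(vals), n)
    arr = np.asarray(vals, dtype=object)
    return arr[rng.permutation(n)]


def make_table1_fixture(seed: int = 0, probable_ad_fraction: float = 0.7,
                        include_frame: bool = True) -> pd.DataFrame:
    """Generate the person-level fixture whose cell counts match the published tables.

    Parameters
    ----------
    seed
        RNG seed; the same seed reproduces identical ids and values.
    probable_ad_fraction
        Share of dementia cases labelled probable AD (the published tables do
        not split dementia by etiology; configurable).
    include_frame
        Also emit nonparticipants, administrative exclusions and the
        unclassifiable in-person participants so that the enrollment-flow
        counts can be recomputed from the fixture.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    serial = 0

    def base_row(group, block):
        nonlocal serial
        serial += 1
        return {"id": f"p{serial:06d}", "group": group, "block": block}

    for b in _block_counts():
        n = b["n"]
        if n == 0:
            continue
        group, block = b["group"], b["block"]
        sexes = _categorical_fill([("female", b["women"]), ("male", n - b["women"])], n, rng)
        edu = _categorical_fill(
            list(zip(_EDU_LEVELS, b["edu"])) + [(np.nan, b["edu_missing"])], n, rng)
        if b["apoe"] is None:
            apoe = np.asarray([np.nan] * n, dtype=object)
        else:
            apoe = _categorical_fill(
                [("noncarrier", b["apoe"][0]), ("carrier", b["apoe"][1]),
                 (np.nan, b["apoe_missing"])], n, rng)
        ages = _draw_ages(rng, n, (group, block))

        if group == "dementia_passive":
            statuses = _status_split(n, probable_ad_fraction, rng)
        elif group.startswith("dementia"):
            statuses = _status_split(n, probable_ad_fraction, rng)
        else:
            statuses = np.asarray([group] * n, dtype=object)

        has_amy = block in ("tau", "amy_only")
        has_tau = block == "tau"
        passive = group == "dementia_passive"
        for i in range(n):
            row = base_row(group, block)
            row.update(
                age=int(ages[i]), sex=sexes[i], education=edu[i], apoe_e4=apoe[i],
                ascertainment="passive" if passive else "active",
                clinical_status=statuses[i],
                enrolled=not passive,
                has_amyloid_pet=has_amy, has_tau_pet=has_tau,
            )
            row["amyloid_suvr"] = _suvr(rng, abnormal_rate=_AMY_RATE[group]) if has_amy else np.nan
            if has_tau:
                t = _suvr(rng, abnormal_rate=_TAU_RATE[group], lo=1.12, hi=1.45, cut=1.25)
                for col in TAU_COLUMNS:
                    row[col] = round(t * float(np.exp(rng.normal(0.0, 0.01))), 3)
            else:
                for col in TAU_COLUMNS:
                    row[col] = np.nan
            rows.append(row)

    if include_frame:
        extra = [
            ("nonparticipant", FIGURE1["nonparticipants"], "nonparticipant"),
            ("excluded", FIGURE1["administrative_exclusions"], "excluded"),
            ("unclassifiable", FIGURE1["unclassifiable"], "active"),
        ]
        for group, n, asc in extra:
            sexes = _categorical_fill([("female", n // 2), ("male", n - n // 2)], n, rng)
            edu_counts = rng.multinomial(n, [0.12, 0.32, 0.36, 0.20])
            edu = _categorical_fill(list(zip(_EDU_LEVELS, edu_counts)), n, rng)
            ages = rng.integers(60, 90, size=n)
            for i in range(n):
                row = base_row(group, "frame")
                row.update(
                    age=int(ages[i]), sex=sexes[i], education=edu[i], apoe_e4=np.nan,
                    ascertainment=asc, clinical_status="unknown",
                    enrolled=(asc == "active"), has_amyloid_pet=False, has_tau_pet=False,
                    amyloid_suvr=np.nan,
                )
                for col in TAU_COLUMNS:
                    row[col] = np.nan
                rows.append(row)

    frame = pd.DataFrame(rows)
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in frame.columns] + ["group", "block"]
    return frame[cols]


_AMY_RATE = {"CU": 0.30, "MCI": 0.52, "dementia_active": 0.80, "dementia_passive": 0.0}
_TAU_RATE = {"CU": 0.17, "MCI": 0.35, "dementia_active": 0.75, "dementia_passive": 0.0}


def _status_split(n, probable_ad_fraction, rng):
    n_pad = int(round(n * probable_ad_fraction))
    return _categorical_fill(
        [("dementia_probable_AD", n_pad), ("dementia_other", n - n_pad)], n, rng)


def _suvr(rng, abnormal_rate, lo=1.30, hi=1.85, cut=1.48):
    """Synthetic SUVR: log-normal around *lo* (normal) or *hi* (abnormal)."""
    if rng.uniform() < abnormal_rate:
        v = float(np.exp(rng.normal(np.log(hi), 0.10)))
        return round(max(v, cut + 0.001), 3)
    v = float(np.exp(rng.normal(np.log(lo), 0.05)))
    return round(min(v, cut - 0.001), 3)
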