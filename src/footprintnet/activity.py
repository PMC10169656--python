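"""Footprint-based protein activity inference.

A regulator's activity is read off the behaviour of its known targets
(its *regulon*): substrate phosphosites for kinases and phosphatases,
transcriptional targets (protein level) for transcription factors.  The
footprint score is the mean signed t-statistic over measured targets,
tested against a permutation null of random target sets.  Independently, a
*phospho-score* infers the activity of any protein carrying measured
regulatory phosphosites (sites annotated as activating or inhibiting their
host).  The two evidence streams are merged by sign agreement.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialTable, bh_adjust

logger = logging.getLogger(__name__)

REGULATOR_CLASSES = ("kinase", "phosphatase", "tf", "other")
MIN_PERMUTATIONS = 100
_EXACT_LIMIT = 500_000  # max enumerated arrangements for the exact null

ACTIVITY_COLUMNS = ["class", "method", "score", "sign", "p_value", "fdr", "n_evidence"]


@dataclass(frozen=True)
class Regulon:
    """One regulator and its signed target set.

    The sign encodes the expected direction of the target's change when the
    regulator is active — for phosphatases as much as for kinases, so no
    extra class-dependent sign flip is ever applied downstream.
    """

    regulator: str
    klass: str
    targets: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.klass not in REGULATOR_CLASSES:
            raise ValueError(f"unknown regulator class {self.klass!r}")
        seen = set()
        for target, sign in self.targets:
            if sign not in (-1, 1):
                raise ValueError(f"regulon sign must be +1/-1 ({self.regulator}->{target})")
            if target in seen:
                raise ValueError(f"duplicate regulon target {self.regulator}->{target}")
            seen.add(target)


class RegulonSet:
    """Mapping regulator -> :class:`Regulon`."""

    def __init__(self, regulons: dict[str, Regulon]):
        self.regulons = dict(sorted(regulons.items()))

    def __len__(self) -> int:
        return len(self.regulons)

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.regulons

    def __getitem__(self, regulator: str) -> Regulon:
        return self.regulons[regulator]

    def items(self):
        return self.regulons.items()

    def subset(self, classes) -> "RegulonSet":
        cls = set(classes)
        return RegulonSet({r: reg for r, reg in self.regulons.items() if reg.klass in cls})

    def flipped(self) -> "RegulonSet":
        """Every target sign negated (used for antisymmetry checks)."""
        return RegulonSet(
            {
                r: Regulon(r, reg.klass, tuple((t, -s) for t, s in reg.targets))
                for r, reg in self.regulons.items()
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"regulator": r, "class": reg.klass, "target": t, "sign": s}
            for r, reg in self.regulons.items()
            for t, s in sorted(reg.targets)
        ]
        return pd.DataFrame(rows, columns=["regulator", "class", "target", "sign"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegulonSet":
        regulons = {}
        for reg, grp in df.groupby("regulator", sort=True):
            klasses = set(grp["class"])
            if len(klasses) != 1:
                raise ValueError(f"regulator {reg!r} has conflicting class labels {klasses}")
            regulons[str(reg)] = Regulon(
                str(reg),
                klasses.pop(),
                tuple((str(t), int(s)) for t, s in zip(grp["target"], grp["sign"])),
            )
        return cls(regulons)


def _finite_t(t: np.ndarray) -> np.ndarray:
    """Clip infinite t-statistics (zero-variance shifts) to a finite ceiling."""
    finite = t[np.isfinite(t)]
    cap = float(np.max(np.abs(finite))) + 1.0 if finite.size else 1.0
    return np.clip(np.nan_to_num(t, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)


def footprint_activity(
    diff: DifferentialTable,
    regulons: RegulonSet,
    min_targets: int = 3,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Footprint activity scores with a permutation null.

    The score of regulator R is the mean of ``regulon_sign * t`` over R's
    measured targets; the null distribution is the same statistic on random
    target sets drawn (without replacement) from all measured features.  The
    two-sided p-value comes from the permutation distribution, the z-score
    from its mean and standard deviation, and FDR control is
    Benjamini-Hochberg across scored regulators.

    With ``exact=True`` the null is enumerated exhaustively over all ordered
    arrangements of measured features into the regulon (only feasible for
    tiny problems); otherwise ``n_perm`` Monte-Carlo draws are used.  Null
    distributions are shared between regulators with the same regulon size
    and sign composition, which leaves the statistic unchanged (the mean is
    exchangeable in the pairing of signs with drawn features).

    Kinase/phosphatase regulons should be scored against the phospho-layer
    table and TF regulons against the proteome-layer table; use
    :meth:`RegulonSet.subset` to split by class before calling.
    """
    if not exact and n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS} for a stable null")
    rng = np.random.default_rng(seed)
    t_all = _finite_t(diff.table["t_stat"].to_numpy(dtype=float))
    measured = pd.Index(diff.table.index)
    n_measured = len(measured)
    pos = {f: i for i, f in enumerate(measured)}

    skipped: list[dict] = []
    rows: list[dict] = []

    for regulator, regulon in regulons.items():
        hits = [(t, s) for t, s in regulon.targets if t in pos]
        n = len(hits)
        if n < min_targets:
            skipped.append({"regulator": regulator, "n_measured_targets": n,
                            "reason": "below_min_targets"})
            continue
        signs = np.array([s for _, s in hits], dtype=float)
        tvals = np.array([t_all[pos[t]] for t, _ in hits], dtype=float)
        score = float(np.mean(signs * tvals))

        null = _null_scores(t_all, signs, n_perm, rng, exact)
        mu, sd = float(null.mean()), float(null.std(ddof=0))
        z = (score - mu) / sd if sd > 0 else 0.0
        dev = np.abs(null - mu)
        obs = abs(score - mu)
        if exact:
            p = float(np.mean(dev >= obs - 1e-12))
        else:
            p = float((1 + np.sum(dev >= obs - 1e-12)) / (len(null) + 1))
        rows.append(
            {
                "protein": regulator,
                "class": regulon.klass,
                "method": "footprint",
                "score": score,
                "sign": int(np.sign(score)),
                "p_value": p,
                "z": z,
                "n_evidence": n,
            }
        )
    if skipped:
        logger.info("footprint: skipped %d regulators below min_targets=%d",
                    len(skipped), min_targets)
    table = pd.DataFrame(rows, columns=["protein", *ACTIVITY_COLUMNS[:-1], "z", "n_evidence"])
    if len(table):
        table = table.set_index("protein").sort_index()
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table = pd.DataFrame(columns=[*ACTIVITY_COLUMNS, "z"]).rename_axis("protein")
    table = table[[c for c in ["class", "method", "score", "sign", "p_value", "fdr", "z",
                               "n_evidence"] if c in table.columns]]
    table.attrs["skipped"] = skipped
    table.attrs["n_measured"] = n_measured
    return table


def _sample_without_replacement(
    rng: np.random.Generator, n_feat: int, n: int, n_draws: int
) -> np.ndarray:
    """(n_draws, n) index matrix, each row a distinct-feature draw."""
    if n > n_feat:
        raise ValueError("regulon larger than the measured feature set")
    if n * n > n_feat:  # dense draws: per-row partial shuffle
        return np.array([rng.choice(n_feat, size=n, replace=False)
                         for _ in range(n_draws)])
    # sparse draws: rejection sampling on rows containing duplicates
    out = rng.integers(0, n_feat, size=(n_draws, n))
    while True:
        bad = (np.diff(np.sort(out, axis=1), axis=1) == 0).any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, n_feat, size=(int(bad.sum()), n))


def _null_scores(
    t_all: np.ndarray, signs: np.ndarray, n_perm: int,
    rng: np.random.Generator, exact: bool,
) -> np.ndarray:
    """Null footprint scores: the regulon's signs applied to random features."""
    n_feat, n = len(t_all), len(signs)
    if exact:
        count = math.perm(n_feat, n)
        if count > _EXACT_LIMIT:
            raise ValueError(
                f"exact null needs {count} arrangements (> {_EXACT_LIMIT}); "
                "use the Monte-Carlo null"
            )
        out = np.empty(count)
        for i, arrangement in enumerate(itertools.permutations(range(n_feat), n)):
            out[i] = float(np.mean(signs * t_all[list(arrangement)]))
        return out
    draws = _sample_without_replacement(rng, n_feat, n, n_perm)
    return (signs * t_all[draws]).mean(axis=1)


def phospho_score(
    diff_phospho: DifferentialTable,
    reg_sites: pd.DataFrame,
    only_significant: bool = True,
    node_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Activity from regulatory phosphosites (activating/inhibiting annotations).

    score(P) = mean over P's measured regulatory sites of (log2fc x effect);
    an activating site going up, or an inhibiting site going down, argues for
    activation.  By default only sites significant in the differential table
    contribute.  Proteins without any contributing site are absent.
    """
    required = {"site", "protein", "effect"}
    if not required.issubset(reg_sites.columns):
        raise ValueError(f"reg_sites needs columns {sorted(required)}")
    tab = diff_phospho.table
    usable = tab[tab["significant"]] if only_significant else tab
    merged = reg_sites.merge(
        usable[["log2fc"]], left_on="site", right_index=True, how="inner"
    )
    rows = []
    for protein, grp in merged.groupby("protein", sort=True):
        contribution = grp["log2fc"].to_numpy() * grp["effect"].to_numpy()
        score = float(np.mean(contribution))
        rows.append(
            {
                "protein": str(protein),
                "class": (node_classes or {}).get(str(protein), "other"),
                "method": "phosphoscore",
                "score": score,
                "sign": int(np.sign(score)),
                "p_value": np.nan,
                "fdr": np.nan,
                "n_evidence": int(len(grp)),
            }
        )
    out = pd.DataFrame(rows, columns=["protein", *ACTIVITY_COLUMNS])
    return out.set_index("protein") if len(out) else out.set_index(
        pd.Index([], name="protein")
    )


def combine_activities(
    footprint: pd.DataFrame, phosphoscore: pd.DataFrame
) -> tuple[pd.DataFrame, list[dict]]:
    """Merge footprint and phospho-score evidence into one activity table.

    Proteins covered by one method keep that row; sign agreement between the
    two methods yields ``method='combined'`` carrying the footprint score and
    p-value; sign conflicts drop the protein (conservative policy) and are
    returned in the conflict report.
    """
    conflicts: list[dict] = []
    rows: dict[str, pd.Series] = {}
    fp_idx = set(footprint.index)
    ps_idx = set(phosphoscore.index)
    for protein in sorted(fp_idx | ps_idx):
        in_fp, in_ps = protein in fp_idx, protein in ps_idx
        if in_fp and not in_ps:
            rows[protein] = footprint.loc[protein]
        elif in_ps and not in_fp:
            rows[protein] = phosphoscore.loc[protein]
        else:
            f, p = footprint.loc[protein], phosphoscore.loc[protein]
            if int(f["sign"]) == int(p["sign"]) and int(f["sign"]) != 0:
                merged = f.copy()
                merged["method"] = "combined"
                merged["n_evidence"] = int(f["n_evidence"]) + int(p["n_evidence"])
                rows[protein] = merged
            else:
                conflicts.append(
                    {
                        "protein": protein,
                        "footprint_sign": int(f["sign"]),
                        "phosphoscore_sign": int(p["sign"]),
                    }
                )
    if conflicts:
        logger.info("combine: dropped %d sign-conflicting proteins", len(conflicts))
    cols = ["class", "method", "score", "sign", "p_value", "fdr", "n_evidence"]
    if rows:
        table = pd.DataFrame(rows).T.rename_axis("protein")
        table = table[[c for c in cols if c in table.columns]]
        for col, typ in [("score", float), ("sign", int), ("p_value", float),
                         ("fdr", float), ("n_evidence", int)]:
            if col in table.columns:
                table[col] = table[col].astype(typ)
    else:
        table = pd.DataFrame(columns=cols).rename_axis("protein")
    return table, conflicts


def compare_activity_profiles(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Pearson/Spearman correlation and sign agreement over shared proteins.

    Used to contrast activity landscapes between two cell contexts; requires
    at least three shared proteins, else the correlations are undefined.
    """
    shared = sorted(set(a.index) & set(b.index))
    out: dict = {"n_shared": len(shared), "shared": shared}
    if len(shared) < 3:
        out.update({"defined": False, "pearson": None, "spearman": None,
                    "sign_agreement": None})
        return out
    sa = a.loc[shared, "score"].to_numpy(dtype=float)
    sb = b.loc[shared, "score"].to_numpy(dtype=float)
    pearson = float(stats.pearsonr(sa, sb).statistic)
    spearman = float(stats.spearmanr(sa, sb).statistic)
    agree = float(np.mean(np.sign(sa) == np.sign(sb)))
    out.update({"defined": True, "pearson": pearson, "spearman": spearman,
                "sign_agreement": agree})
    return out
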