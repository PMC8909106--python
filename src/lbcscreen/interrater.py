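"""Fleiss' kappa concordance analysis for multi-rater cytology calls.

Ratings use the Bethesda-style subclass vocabulary {NILM, ASC-US, ASC-H,
LSIL, HSIL, SCC, ADC} (CIS is accepted on input and treated as neoplastic
in the binary collapse).  Fleiss' kappa for N subjects rated by n raters
over K categories, with ``n_ij`` raters placing subject i in category j:

    P_i   = [sum_j n_ij (n_ij - 1)] / [n (n - 1)]
    P-bar = mean_i P_i
    p_j   = sum_i n_ij / (N n);   P_e = sum_j p_j^2
    kappa = (P-bar - P_e) / (1 - P_e)

When every rating in the table falls in a single category, ``P_e = 1`` and
the ratio is undefined; agreement is then complete, and kappa is reported
as 1.0 (the convention the published concordance table uses for the
unanimous binary-neoplastic subset).

The package bundles the rating table of the published interobserver study —
16 cytoscreeners reviewing 10 LBC slides (8 reported NILM, 2 neoplastic) —
as a text fixture; kappa on its 16-rater columns reproduces the published
values exactly.  The study's 8-senior-rater column does not reproduce under
any subset scheme we tried and is documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import ConfigError

SUBCLASSES = ("NILM", "ASC-US", "ASC-H", "LSIL", "HSIL", "SCC", "ADC")
#: accepted on input; collapses to neoplastic
EXTRA_CATEGORIES = ("CIS",)
BINARY = ("NILM", "neoplastic")

#: agreement bins of the standard interpretation scale; upper bounds
#: inclusive, a boundary value falls in the lower bin containing it
_SCALE = [(0.0, "poor"), (0.20, "slight"), (0.40, "fair"),
          (0.60, "moderate"), (0.80, "substantial"), (1.0, "almost perfect")]


@dataclass
class RatingTable:
    """Cases x raters categorical calls plus the per-case report label."""

    case_ids: list[str]
    report_labels: list[str]       # NILM or a neoplastic subclass
    raters: list[str]
    ratings: np.ndarray            # (N, n) array of category strings
    scheme: str = "subclass"       # "subclass" | "binary"

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=object)
        n_cases = len(self.case_ids)
        if self.ratings.shape != (n_cases, len(self.raters)):
            raise ConfigError("ragged ratings matrix")
        vocab = set(self.categories) | set(EXTRA_CATEGORIES)
        bad = {r for r in self.ratings.ravel() if r not in vocab}
        if bad:
            raise ConfigError(f"unknown rating categories: {sorted(bad)}")

    @property
    def categories(self) -> tuple[str, ...]:
        return BINARY if self.scheme == "binary" else SUBCLASSES

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    def counts(self) -> np.ndarray:
        """n_ij matrix (cases x categories); CIS counts as neoplastic only
        after binary collapse, otherwise as its own input column appended."""
        cats = list(self.categories)
        if self.scheme == "subclass":
            cats += [c for c in EXTRA_CATEGORIES
                     if c in set(self.ratings.ravel())]
        out = np.zeros((len(self.case_ids), len(cats)), dtype=int)
        for j, cat in enumerate(cats):
            out[:, j] = (self.ratings == cat).sum(axis=1)
        return out

    @property
    def report_binary(self) -> list[str]:
        return ["NILM" if lab == "NILM" else "neoplastic"
                for lab in self.report_labels]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingTable":
        """CSV with columns case_id, report, then one column per rater."""
        df = pd.read_csv(path, dtype=str)
        if "case_id" not in df.columns or "report" not in df.columns:
            raise ConfigError(f"{path}: need case_id and report columns")
        raters = [c for c in df.columns if c not in ("case_id", "report")]
        if not raters:
            raise ConfigError(f"{path}: no rater columns")
        return cls(case_ids=df["case_id"].tolist(),
                   report_labels=df["report"].tolist(),
                   raters=raters,
                   ratings=df[raters].to_numpy(dtype=object))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.ratings, columns=self.raters)
        df.insert(0, "report", self.report_labels)
        df.insert(0, "case_id", self.case_ids)
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_bar: float
    p_e: float
    scheme: str
    subset: str
    interpretation: str


def load_rater_study() -> RatingTable:
    """The bundled 16-cytoscreener / 10-slide interobserver rating table."""
    ref = resources.files("lbcscreen.data") / "rater_study.csv"
    with resources.as_file(ref) as p:
        return RatingTable.from_csv(p)


def fleiss_kappa(table: RatingTable, subset: str = "all") -> KappaResult:
    """Fleiss' kappa over the table's categories (see module docstring)."""
    if table.n_raters < 2 or not table.case_ids:
        raise ConfigError("need >= 2 raters and >= 1 subject")
    counts = table.counts().astype(float)
    n = table.n_raters
    big_n = counts.shape[0]
    p_i = ((counts ** 2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (big_n * n)
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0:
        kappa = 1.0 if p_bar == 1.0 else float("nan")
    else:
        kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, p_bar=p_bar, p_e=p_e,
                       scheme=table.scheme, subset=subset,
                       interpretation=interpretation_label(kappa))


def collapse_binary(table: RatingTable) -> RatingTable:
    """Map every non-NILM call (incl. CIS) to 'neoplastic'."""
    mapped = np.where(table.ratings == "NILM", "NILM", "neoplastic")
    return replace(table, ratings=mapped.astype(object), scheme="binary")


def subset_cases(table: RatingTable, subset: str) -> RatingTable:
    """Filter cases by report label: NILM-cases, neoplastic-cases or all."""
    if subset == "all":
        keep = list(range(len(table.case_ids)))
    elif subset == "NILM-cases":
        keep = [i for i, lab in enumerate(table.report_binary)
                if lab == "NILM"]
    elif subset == "neoplastic-cases":
        keep = [i for i, lab in enumerate(table.report_binary)
                if lab == "neoplastic"]
    else:
        raise ConfigError(f"unknown subset {subset!r}")
    if not keep:
        raise ConfigError(f"subset {subset!r} selects no cases")
    return replace(table,
                   case_ids=[table.case_ids[i] for i in keep],
                   report_labels=[table.report_labels[i] for i in keep],
                   ratings=table.ratings[keep])


def kappa_for(table: RatingTable, scheme: str = "subclass",
              subset: str = "all") -> KappaResult:
    """Convenience: subset, optionally collapse, then kappa."""
    t = subset_cases(table, subset)
    if scheme == "binary":
        t = collapse_binary(t)
    elif scheme != "subclass":
        raise ConfigError(f"unknown scheme {scheme!r}")
    return fleiss_kappa(t, subset=subset)


def interpretation_label(kappa: float) -> str:
    """Ordinal agreement label on the standard interpretation scale."""
    if np.isnan(kappa):
        return "undefined"
    if kappa <= 0.0:
        return "poor"
    for upper, label in _SCALE[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"
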