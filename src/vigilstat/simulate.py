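"""Seeded generator of FAERS-like spontaneous-report corpora.

The generator emulates the statistical structure that 2x2 disproportionality
assumes: each report is exposed to a target drug combination with a fixed
probability; given exposure status, each preferred term enters the report's
reaction set as an independent Bernoulli draw with probability

    p_background * RR_effective   (capped at 1),

where RR_effective is the configured reporting-rate ratio when the report's
suspect-drug set matches an injected association and 1 otherwise.  Reports
are guaranteed at least one reaction by redrawing the whole reaction vector,
so the per-PT inclusion probability conditional on a non-empty report has
the exact closed form p_j / (1 - prod_k(1 - p_k)) used by
:func:`expected_two_by_two`.

Demographics (sex, age band, reporter occupation) and the seriousness
outcome are independent categorical draws; at most one serious outcome is
assigned per report so seriousness blocks partition the cohort cleanly.  A
configurable fraction of reports is re-emitted with an incremented case
version to exercise deduplication.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .contingency import TwoByTwo
from .reports import (
    DrugEntry,
    DrugRole,
    Occupation,
    Outcome,
    ReportRecord,
    ReportSet,
    Sex,
)

logger = logging.getLogger("vigilstat")

__all__ = [
    "PtSpec",
    "InjectedSignal",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "expected_two_by_two",
    "independence_config",
    "signal_config",
]

#: Age bands (label, low, high) matched to the demographic summary bands;
#: ages are drawn uniformly within the sampled band.
_AGE_BANDS = {
    "<18": (1.0, 18.0),
    "18-44": (18.0, 45.0),
    "45-64": (45.0, 65.0),
    "65-74": (65.0, 75.0),
    ">=75": (75.0, 100.0),
}

# Demographic mix of a large statin/fibrate cohort: slight male majority,
# mostly middle-aged and older patients, consumer reports the largest
# reporter class, just under half of reports serious with hospitalization
# dominating.
DEFAULT_SEX_PROBS = {"M": 0.545, "F": 0.414, "UNK": 0.041}
DEFAULT_AGE_PROBS = {
    "<18": 0.002,
    "18-44": 0.044,
    "45-64": 0.313,
    "65-74": 0.164,
    ">=75": 0.083,
    "unknown": 0.394,
}
DEFAULT_OCC_PROBS = {
    "MD": 0.216,
    "PH": 0.061,
    "OT": 0.147,
    "LW": 0.019,
    "CN": 0.386,
    "UNK": 0.171,
}
DEFAULT_OUTCOME_PROBS = {
    "none": 0.566,
    "DE": 0.056,
    "HO": 0.310,
    "CA": 0.0003,
    "DS": 0.0337,
    "LT": 0.034,
}


@dataclass(frozen=True)
class PtSpec:
    """One preferred term: name, organ class, background reporting probability."""

    pt: str
    soc: str
    p_background: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_background <= 1):
            raise ValueError(f"{self.pt}: p_background outside [0, 1]")


@dataclass(frozen=True)
class InjectedSignal:
    """A drug-set/PT association with reporting-rate ratio RR (>= 0)."""

    drugs: frozenset[str]
    pt: str
    rr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        if self.rr < 0:
            raise ValueError("rr must be >= 0")


@dataclass
class GeneratorConfig:
    """Full stochastic specification of a synthetic report corpus."""

    n_reports: int
    drug_catalog: list[tuple[str, float]]
    target_combo: tuple[str, ...]
    exposure_prob: float
    pt_catalog: list[PtSpec]
    injected_signals: list[InjectedSignal] = field(default_factory=list)
    sex_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_band_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_PROBS))
    occupation_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OCC_PROBS))
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    duplicate_fraction: float = 0.0
    #: optional sex-specific effects: PT -> multiplicative factor applied to
    #: the PT's inclusion probability for female patients (capped at 1)
    female_rr: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if not (0 <= self.exposure_prob <= 1):
            raise ValueError("exposure_prob outside [0, 1]")
        if not (0 <= self.duplicate_fraction <= 0.5):
            raise ValueError("duplicate_fraction outside [0, 0.5]")
        for probs, what in (
            (self.sex_probs, "sex_probs"),
            (self.age_band_probs, "age_band_probs"),
            (self.occupation_probs, "occupation_probs"),
            (self.outcome_probs, "outcome_probs"),
        ):
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"{what} must sum to 1 (got {total})")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{what} has a negative probability")
        for _, p in self.drug_catalog:
            if not (0 <= p <= 1):
                raise ValueError("drug marginal probability outside [0, 1]")

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_reports": self.n_reports,
            "drug_catalog": [[n, float(p)] for n, p in self.drug_catalog],
            "target_combo": list(self.target_combo),
            "exposure_prob": self.exposure_prob,
            "pt_catalog": [[s.pt, s.soc, float(s.p_background)] for s in self.pt_catalog],
            "injected_signals": [
                {"drugs": sorted(s.drugs), "pt": s.pt, "rr": float(s.rr)}
                for s in self.injected_signals
            ],
            "sex_probs": dict(self.sex_probs),
            "age_band_probs": dict(self.age_band_probs),
            "occupation_probs": dict(self.occupation_probs),
            "outcome_probs": dict(self.outcome_probs),
            "duplicate_fraction": self.duplicate_fraction,
            "female_rr": {k: float(v) for k, v in self.female_rr.items()},
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(
                n_reports=int(data["n_reports"]),
                drug_catalog=[(str(n), float(p)) for n, p in data["drug_catalog"]],
                target_combo=tuple(data["target_combo"]),
                exposure_prob=float(data["exposure_prob"]),
                pt_catalog=[PtSpec(str(p), str(s), float(q)) for p, s, q in data["pt_catalog"]],
                injected_signals=[
                    InjectedSignal(frozenset(d["drugs"]), str(d["pt"]), float(d["rr"]))
                    for d in data.get("injected_signals", [])
                ],
                sex_probs=data.get("sex_probs", dict(DEFAULT_SEX_PROBS)),
                age_band_probs=data.get("age_band_probs", dict(DEFAULT_AGE_PROBS)),
                occupation_probs=data.get("occupation_probs", dict(DEFAULT_OCC_PROBS)),
                outcome_probs=data.get("outcome_probs", dict(DEFAULT_OUTCOME_PROBS)),
                duplicate_fraction=float(data.get("duplicate_fraction", 0.0)),
                female_rr={str(k): float(v) for k, v in (data.get("female_rr") or {}).items()},
                seed=int(data.get("seed", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid generator config {path}: {exc}") from exc


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    exposed_case_ids: set[str]
    expected_pt_counts: dict[str, float]
    injected: list[InjectedSignal]


def _effective_probs(cfg: GeneratorConfig, exposed: bool) -> np.ndarray:
    """Per-PT inclusion probabilities for one exposure status, capped at 1."""
    probs = np.array([s.p_background for s in cfg.pt_catalog], dtype=float)
    if exposed:
        combo = frozenset(d.casefold() for d in cfg.target_combo)
        index = {s.pt: i for i, s in enumerate(cfg.pt_catalog)}
        capped = []
        for sig in cfg.injected_signals:
            if frozenset(d.casefold() for d in sig.drugs) <= combo:
                i = index.get(sig.pt)
                if i is None:
                    raise KeyError(f"injected signal PT {sig.pt!r} not in pt_catalog")
                raw = probs[i] * sig.rr
                if raw > 1:
                    capped.append(sig.pt)
                probs[i] = min(1.0, raw)
        if capped:
            logger.warning("probability cap hit for PTs: %s", ", ".join(capped))
    return probs


def generate(cfg: GeneratorConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw a corpus and its ground truth; fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    pts = [s.pt for s in cfg.pt_catalog]
    p_exp = _effective_probs(cfg, exposed=True)
    p_bg = _effective_probs(cfg, exposed=False)

    sex_labels, sex_p = _unzip(cfg.sex_probs)
    age_labels, age_p = _unzip(cfg.age_band_probs)
    occ_labels, occ_p = _unzip(cfg.occupation_probs)
    out_labels, out_p = _unzip(cfg.outcome_probs)

    width = max(6, len(str(max(cfg.n_reports, 1))))
    reports: list[ReportRecord] = []
    exposed_ids: set[str] = set()
    for i in range(cfg.n_reports):
        cid = f"SYN{i:0{width}d}"
        is_exposed = bool(rng.random() < cfg.exposure_prob)
        if is_exposed:
            exposed_ids.add(cid)
            drugs = tuple(
                DrugEntry(name, DrugRole.PRIMARY_SUSPECT) for name in cfg.target_combo
            )
            probs = p_exp
        else:
            drugs = _background_drugs(cfg, rng)
            probs = p_bg
        sex = Sex(sex_labels[rng.choice(len(sex_labels), p=sex_p)])
        if cfg.female_rr and sex is Sex.FEMALE:
            probs = probs.copy()
            for j, spec in enumerate(cfg.pt_catalog):
                f = cfg.female_rr.get(spec.pt)
                if f is not None:
                    probs[j] = min(1.0, probs[j] * f)
        reactions = _draw_reactions(pts, probs, rng)
        band = age_labels[rng.choice(len(age_labels), p=age_p)]
        if band == "unknown":
            age = None
        else:
            lo, hi = _AGE_BANDS[band]
            age = float(np.floor(rng.uniform(lo, hi)))
        occ = Occupation(occ_labels[rng.choice(len(occ_labels), p=occ_p)])
        out_tok = out_labels[rng.choice(len(out_labels), p=out_p)]
        outcomes = frozenset() if out_tok == "none" else frozenset({Outcome(out_tok)})
        reports.append(
            ReportRecord(
                case_id=cid,
                case_version=1,
                drugs=drugs,
                reactions=reactions,
                sex=sex,
                age_years=age,
                occupation=occ,
                outcomes=outcomes,
            )
        )

    if cfg.duplicate_fraction > 0 and reports:
        n_dup = int(round(cfg.duplicate_fraction * len(reports)))
        dup_idx = rng.choice(len(reports), size=n_dup, replace=False)
        for i in sorted(dup_idx):
            orig = reports[i]
            reports.append(
                ReportRecord(
                    case_id=orig.case_id,
                    case_version=orig.case_version + 1,
                    drugs=orig.drugs,
                    reactions=orig.reactions,
                    sex=orig.sex,
                    age_years=orig.age_years,
                    occupation=orig.occupation,
                    outcomes=orig.outcomes,
                )
            )

    q_exp = float(np.prod(1 - p_exp))
    q_bg = float(np.prod(1 - p_bg))
    n_exp = cfg.n_reports * cfg.exposure_prob
    n_bg = cfg.n_reports * (1 - cfg.exposure_prob)
    expected = {}
    for j, pt in enumerate(pts):
        expected[pt] = n_exp * _cond(p_exp, j, q_exp) + n_bg * _cond(p_bg, j, q_bg)

    truth = GroundTruth(
        exposed_case_ids=exposed_ids,
        expected_pt_counts=expected,
        injected=list(cfg.injected_signals),
    )
    rs = ReportSet(
        reports,
        [
            f"generate(seed={cfg.seed}): {cfg.n_reports} reports "
            f"({len(exposed_ids)} exposed), {len(reports) - cfg.n_reports} duplicates"
        ],
    )
    return rs, truth


def _cond(probs: np.ndarray, j: int, q_none: float) -> float:
    """P(PT j present | at least one PT present) under independent draws."""
    if q_none >= 1.0:
        return 0.0
    return float(probs[j]) / (1.0 - q_none)


def _unzip(probs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    return labels, p / p.sum()


def _background_drugs(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[DrugEntry, ...]:
    """Suspect-drug list for a non-exposed report.

    Each catalog drug appears independently with its marginal probability;
    the first sampled drug is the primary suspect, the rest concomitant.  A
    background report never carries the full target combination as primary
    suspects, so the exposed set defined by the suspect-drug filter equals
    the generator's ground truth exactly.
    """
    combo = {d.casefold() for d in cfg.target_combo}
    names = [n for n, p in cfg.drug_catalog if rng.random() < p]
    present = {n.casefold() for n in names}
    if combo and combo <= present:
        # drop one combo member to keep ground truth exact
        drop = sorted(combo)[0]
        names = [n for n in names if n.casefold() != drop]
    if not names:
        pool = [n for n, _ in cfg.drug_catalog] or ["unspecified drug"]
        names = [pool[rng.choice(len(pool))]]
    return tuple(
        DrugEntry(n, DrugRole.PRIMARY_SUSPECT if i == 0 else DrugRole.CONCOMITANT)
        for i, n in enumerate(names)
    )


def _draw_reactions(
    pts: Sequence[str], probs: np.ndarray, rng: np.random.Generator
) -> frozenset[str]:
    """Independent Bernoulli per PT, redrawn until at least one is present."""
    while True:
        mask = rng.random(len(pts)) < probs
        if mask.any():
            return frozenset(pt for pt, m in zip(pts, mask) if m)


def expected_two_by_two(cfg: GeneratorConfig, pt: str) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) under the generative model.

    Expectations are per generated (pre-duplication) corpus with the
    exposed/background split defined by target-combo exposure; the at-least-
    one-reaction redraw is accounted for exactly via the conditional
    inclusion probability p_j / (1 - prod(1 - p_k)).
    """
    pts = [s.pt for s in cfg.pt_catalog]
    if pt not in pts:
        raise KeyError(f"unknown PT {pt!r}")
    j = pts.index(pt)
    p_exp = _effective_probs(cfg, exposed=True)
    p_bg = _effective_probs(cfg, exposed=False)
    q_exp = float(np.prod(1 - p_exp))
    q_bg = float(np.prod(1 - p_bg))
    n_exp = cfg.n_reports * cfg.exposure_prob
    n_bg = cfg.n_reports * (1 - cfg.exposure_prob)
    a = n_exp * _cond(p_exp, j, q_exp)
    pairs_exp = n_exp * sum(_cond(p_exp, k, q_exp) for k in range(len(pts)))
    c = n_bg * _cond(p_bg, j, q_bg)
    pairs_bg = n_bg * sum(_cond(p_bg, k, q_bg) for k in range(len(pts)))
    return a, pairs_exp - a, c, pairs_bg - c


# --------------------------------------------------------------------------
# Study-condition factories


def _pt_grid(n_pts: int, mean_reactions: float = 3.0) -> list[PtSpec]:
    """A deterministic catalog of n_pts terms whose background probabilities
    spread over two orders of magnitude and sum to ``mean_reactions``."""
    raw = np.logspace(0, -2, n_pts)
    probs = raw / raw.sum() * mean_reactions
    probs = np.minimum(probs, 0.5)
    socs = [f"SOC{i % 12:02d}" for i in range(n_pts)]
    return [
        PtSpec(pt=f"PT{i:03d}", soc=socs[i], p_background=float(p))
        for i, p in enumerate(probs)
    ]


_DEFAULT_CATALOG = [
    ("rosuvastatin", 0.06),
    ("fenofibrate", 0.05),
    ("atorvastatin", 0.10),
    ("simvastatin", 0.08),
    ("metformin", 0.12),
    ("aspirin", 0.15),
    ("lisinopril", 0.10),
    ("amlodipine", 0.09),
    ("omeprazole", 0.11),
    ("levothyroxine", 0.07),
]


def independence_config(
    n_reports: int = 2000,
    n_pts: int = 200,
    *,
    exposure_prob: float = 0.1,
    seed: int = 0,
) -> GeneratorConfig:
    """Null-model corpus: every reporting-rate ratio is 1."""
    return GeneratorConfig(
        n_reports=n_reports,
        drug_catalog=list(_DEFAULT_CATALOG),
        target_combo=("rosuvastatin", "fenofibrate"),
        exposure_prob=exposure_prob,
        pt_catalog=_pt_grid(n_pts),
        injected_signals=[],
        seed=seed,
    )


def signal_config(
    n_reports: int = 2000,
    n_pts: int = 200,
    *,
    exposure_prob: float = 0.1,
    rr: float = 10.0,
    signal_pt_background: float = 0.01,
    seed: int = 0,
) -> GeneratorConfig:
    """Corpus with one injected drug-combination/PT association.

    Defaults give the injected PT an expected exposed count of
    n_reports * exposure_prob * p_background * rr = 20.
    """
    catalog = _pt_grid(n_pts)
    # pin the injected PT's background probability
    target_pt = "PT_SIGNAL"
    catalog = catalog[:-1] + [PtSpec(target_pt, "SOC00", signal_pt_background)]
    combo = ("rosuvastatin", "fenofibrate")
    return GeneratorConfig(
        n_reports=n_reports,
        drug_catalog=list(_DEFAULT_CATALOG),
        target_combo=combo,
        exposure_prob=exposure_prob,
        pt_catalog=catalog,
        injected_signals=[InjectedSignal(frozenset(combo), target_pt, rr)],
        seed=seed,
    )
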