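"""Motif-based kinase-substrate prediction and Fisher's-exact enrichment.

Kinases recognise short sequence motifs around their substrate residues; a
GPS-family scorer exploits this by scoring each candidate +/-7 flanking
window against a kinase's known substrate windows with a substitution matrix
(BLOSUM62 by default), summed over the 15 aligned positions and averaged over
the reference windows. A per-kinase cutoff is calibrated so that a chosen
false-positive rate of background windows (the experiment's own windows with
shuffled flanks) would be called substrates. Enrichment of a kinase's
predicted substrates among up- or down-regulated sites, versus the remainder
of quantified class-I sites, is tested with a one-sided Fisher's exact test,
and significant kinases are rolled up by family (CAMK, CMGC, AGC, ...).

:class:`KinaseEnrichmentModel` packages calibration, prediction and the two
direction-set enrichment scans; ``fit()`` returns
:class:`KinaseEnrichmentResults` with the per-kinase 2x2 tables, odds ratios,
p values, a family summary and ``summary()``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .io import AMINO_ACIDS, CENTER, PAD, WINDOW_LENGTH, SiteRecord

logger = logging.getLogger(__name__)

_ALPHABET = AMINO_ACIDS + PAD
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_PAD_CODE = _CODE[PAD]


@dataclass
class KinaseSpec:
    """A kinase's reference substrate windows plus its calibrated cutoff."""

    name: str
    family: str
    reference_windows: list[str]
    residue_class: str | None = None  # "ST" or "Y"; inferred if None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.reference_windows:
            raise ValueError(f"kinase {self.name!r} has no reference windows")
        centers = set()
        for w in self.reference_windows:
            if len(w) != WINDOW_LENGTH:
                raise ValueError(
                    f"kinase {self.name!r}: reference window length {len(w)} != "
                    f"{WINDOW_LENGTH}"
                )
            if w[CENTER] not in "STY":
                raise ValueError(
                    f"kinase {self.name!r}: window center {w[CENTER]!r} not S/T/Y"
                )
            centers.add(w[CENTER])
        if self.residue_class is None:
            self.residue_class = "Y" if centers == {"Y"} else "ST"
        if self.residue_class not in ("ST", "Y"):
            raise ValueError(f"residue_class must be 'ST' or 'Y', got {self.residue_class!r}")


@dataclass
class KSRelation:
    """Predicted kinase -> substrate-site links."""

    kinase: str
    predicted_site_ids: frozenset[str]


@dataclass
class ContingencyResult:
    """One kinase's 2x2 enrichment outcome for one regulated set."""

    kinase: str
    a: int  # regulated & substrate
    b: int  # regulated & non-substrate
    c: int  # non-regulated & substrate
    d: int  # non-regulated & non-substrate
    odds_ratio: float
    p_value: float
    direction: str = ""  # which regulated set ("up"/"down") was tested


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def load_substitution_matrix(name_or_path: str = "BLOSUM62") -> np.ndarray:
    """Return a 21x21 score array over the package alphabet (20 aa + pad).

    Accepts a matrix name bundled with Biopython (e.g. ``BLOSUM62``) or a
    path to an NCBI-format matrix file. Any position aligned to the padding
    character scores 0.
    """
    try:
        mat = substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        mat = substitution_matrices.read(name_or_path)
    out = np.zeros((21, 21), dtype=float)
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            out[i, j] = mat[x, y]
    return out


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    """Encode 15-mer windows into an (n, 15) integer code array."""
    arr = np.empty((len(windows), WINDOW_LENGTH), dtype=np.int8)
    for i, w in enumerate(windows):
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"window length {len(w)} != {WINDOW_LENGTH}: {w!r}")
        try:
            arr[i] = [_CODE[c] for c in w]
        except KeyError as e:
            raise ValueError(f"character {e.args[0]!r} outside alphabet in {w!r}") from e
    return arr


def window_similarity(
    w1: str, w2: str, substitution_matrix: np.ndarray | None = None
) -> float:
    """Position-summed substitution score of two aligned 15-mer windows."""
    m = load_substitution_matrix() if substitution_matrix is None else substitution_matrix
    c1 = encode_windows([w1])[0]
    c2 = encode_windows([w2])[0]
    return float(m[c1, c2].sum())


def score_windows(
    queries: Sequence[str] | np.ndarray,
    references: Sequence[str] | np.ndarray,
    substitution_matrix: np.ndarray,
) -> np.ndarray:
    """Mean reference-window similarity for each query window (vectorised)."""
    q = queries if isinstance(queries, np.ndarray) else encode_windows(queries)
    r = references if isinstance(references, np.ndarray) else encode_windows(references)
    # (nq, nr, 15) lookup summed over positions, averaged over references
    scores = substitution_matrix[q[:, None, :], r[None, :, :]].sum(axis=2)
    return scores.mean(axis=1)


def score_site(
    window: str, kinase: KinaseSpec, substitution_matrix: np.ndarray | None = None
) -> float:
    """Score one window against a kinase: mean similarity to its references."""
    m = load_substitution_matrix() if substitution_matrix is None else substitution_matrix
    return float(score_windows([window], kinase.reference_windows, m)[0])


# ---------------------------------------------------------------------------
# cutoff calibration
# ---------------------------------------------------------------------------


def shuffle_flanks(
    windows: Sequence[str], n: int, rng: np.random.Generator
) -> list[str]:
    """Background windows: sample experiment windows and permute their flanks.

    The center residue is kept fixed, so the background preserves both the
    amino-acid composition and the S/T/Y center mix of the experiment.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to build a background from")
    idx = rng.integers(0, len(windows), size=n)
    out = []
    for i in idx:
        w = windows[i]
        flanks = list(w[:CENTER] + w[CENTER + 1 :])
        rng.shuffle(flanks)
        out.append("".join(flanks[:CENTER]) + w[CENTER] + "".join(flanks[CENTER:]))
    return out


def calibrate_cutoff(
    kinase: KinaseSpec,
    background_windows: Sequence[str],
    fpr: float = 0.02,
    substitution_matrix: np.ndarray | None = None,
) -> float:
    """Score cutoff at the (1 - fpr) empirical quantile of background scores.

    The cutoff is the smallest value such that the fraction of background
    windows scoring >= cutoff is <= fpr (ties resolved upward); for
    fpr < 1/n this exceeds every background score.
    """
    if not 0.0 < fpr <= 1.0:
        raise ValueError(f"fpr must be in (0, 1], got {fpr}")
    if len(background_windows) == 0:
        raise ValueError("background is empty")
    m = load_substitution_matrix() if substitution_matrix is None else substitution_matrix
    scores = score_windows(list(background_windows), kinase.reference_windows, m)
    n = len(scores)
    allowed = int(math.floor(fpr * n))
    desc = np.sort(scores)[::-1]
    if allowed == 0:
        return float(np.nextafter(desc[0], np.inf))
    cand = desc[allowed - 1]
    if np.sum(scores >= cand) <= allowed:
        return float(cand)
    # ties at the candidate push the count over fpr: move just above it
    return float(np.nextafter(cand, np.inf))


def predict_substrates(
    sites: Sequence[SiteRecord],
    kinases: Sequence[KinaseSpec],
    substitution_matrix: np.ndarray | None = None,
) -> list[KSRelation]:
    """Predict each kinase's substrate sites among the given class-I sites.

    A site is predicted for a kinase when its center residue matches the
    kinase's residue class (S/T vs Y) and its window score reaches the
    kinase's calibrated cutoff.
    """
    m = load_substitution_matrix() if substitution_matrix is None else substitution_matrix
    site_ids = np.array([s.site_id for s in sites])
    residues = np.array([s.residue for s in sites])
    codes = encode_windows([s.window for s in sites]) if sites else np.empty((0, 15), np.int8)
    relations = []
    for k in kinases:
        if k.cutoff is None:
            raise ValueError(f"kinase {k.name!r} has no calibrated cutoff")
        gate = np.isin(residues, list(k.residue_class))
        predicted: frozenset[str] = frozenset()
        if gate.any():
            scores = score_windows(codes[gate], encode_windows(k.reference_windows), m)
            predicted = frozenset(site_ids[gate][scores >= k.cutoff])
        relations.append(KSRelation(k.name, predicted))
    return relations


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def fisher_enrich(
    relation: KSRelation,
    regulated: Iterable[str],
    universe: Iterable[str],
    direction: str = "",
) -> ContingencyResult:
    """One-sided Fisher's exact enrichment of predicted substrates.

    The 2x2 table contrasts regulated sites against the remainder of the
    universe, split by predicted-substrate membership; p is the upper
    hypergeometric tail (enrichment only).
    """
    regulated = frozenset(regulated)
    universe = frozenset(universe)
    if not regulated <= universe:
        raise ValueError("regulated set is not a subset of the universe")
    predicted = relation.predicted_site_ids & universe
    a = len(predicted & regulated)
    b = len(regulated) - a
    c = len(predicted) - a
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        odds = math.inf if a > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(relation.kinase, a, b, c, d, odds, float(p), direction)


def family_summary(
    results: Sequence[ContingencyResult],
    specs: Sequence[KinaseSpec],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family counts of significantly enriched kinases, by direction set."""
    family_of = {s.name: s.family for s in specs}
    for r in results:
        if r.kinase not in family_of:
            raise ValueError(f"unknown kinase {r.kinase!r} in results")
    rows: dict[str, dict[str, int]] = {}
    for s in specs:
        rows.setdefault(s.family, {"n_enriched_up": 0, "n_enriched_down": 0})
    for r in results:
        if r.p_value < alpha and r.direction in ("up", "down"):
            rows[family_of[r.kinase]][f"n_enriched_{r.direction}"] += 1
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("family")
        .sort_index()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class KinaseEnrichmentModel:
    """Kinase-substrate prediction + enrichment over up/down regulated sets.

    Parameters
    ----------
    sites
        Quantified class-I :class:`SiteRecord` list (the test universe).
    kinases
        Kinase reference specs; cutoffs are calibrated during ``fit``.
    up_ids, down_ids
        Regulated site-id sets from the differential analysis.
    fpr
        Nominal background false-positive rate for the score cutoffs.
    n_background
        Background windows (shuffled flanks) generated per residue class.
    """

    def __init__(
        self,
        sites: Sequence[SiteRecord],
        kinases: Sequence[KinaseSpec],
        up_ids: Iterable[str],
        down_ids: Iterable[str],
        fpr: float = 0.02,
        substitution_matrix: str | np.ndarray = "BLOSUM62",
        n_background: int = 1000,
        seed: int = 0,
    ):
        self.sites = list(sites)
        self.kinases = list(kinases)
        self.up_ids = frozenset(up_ids)
        self.down_ids = frozenset(down_ids)
        self.fpr = fpr
        self.n_background = n_background
        self.seed = seed
        if isinstance(substitution_matrix, np.ndarray):
            self.matrix = substitution_matrix
        else:
            self.matrix = load_substitution_matrix(substitution_matrix)
        self.universe = frozenset(s.site_id for s in self.sites)
        missing = (self.up_ids | self.down_ids) - self.universe
        if missing:
            raise ValueError(
                f"{len(missing)} regulated site ids are not in the site universe"
            )

    def fit(self, alpha: float = 0.05) -> "KinaseEnrichmentResults":
        rng = np.random.default_rng(self.seed)
        by_class = {
            "ST": [s.window for s in self.sites if s.residue in "ST"],
            "Y": [s.window for s in self.sites if s.residue == "Y"],
        }
        backgrounds = {
            rc: shuffle_flanks(ws, self.n_background, rng) if ws else []
            for rc, ws in by_class.items()
        }
        for k in self.kinases:
            bg = backgrounds[k.residue_class]
            if not bg:
                raise ValueError(
                    f"no background windows for residue class {k.residue_class!r}"
                )
            k.cutoff = calibrate_cutoff(k, bg, self.fpr, self.matrix)
        relations = predict_substrates(self.sites, self.kinases, self.matrix)
        results = []
        for rel in relations:
            results.append(fisher_enrich(rel, self.up_ids, self.universe, "up"))
            results.append(fisher_enrich(rel, self.down_ids, self.universe, "down"))
        return KinaseEnrichmentResults(self, relations, results, alpha, backgrounds)


class KinaseEnrichmentResults:
    def __init__(
        self,
        model: KinaseEnrichmentModel,
        relations: list[KSRelation],
        results: list[ContingencyResult],
        alpha: float,
        backgrounds: dict[str, list[str]] | None = None,
    ):
        self.model = model
        self.relations = relations
        self.results = results
        self.alpha = alpha
        self.backgrounds = backgrounds or {}
        self.frame = pd.DataFrame(
            {
                "kinase": [r.kinase for r in results],
                "family": [
                    {s.name: s.family for s in model.kinases}[r.kinase] for r in results
                ],
                "direction_set": [r.direction for r in results],
                "a": [r.a for r in results],
                "b": [r.b for r in results],
                "c": [r.c for r in results],
                "d": [r.d for r in results],
                "odds_ratio": [r.odds_ratio for r in results],
                "p_value": [r.p_value for r in results],
            }
        )

    def top(self, n: int = 20, direction: str = "up") -> pd.DataFrame:
        """Top kinases for one direction set, ranked by p (substrate count
        a as tiebreak)."""
        sub = self.frame[self.frame["direction_set"] == direction].copy()
        sub = sub.sort_values(["p_value", "a"], ascending=[True, False], kind="mergesort")
        return sub.head(n).reset_index(drop=True)

    def family_summary(self) -> pd.DataFrame:
        return family_summary(self.results, self.model.kinases, self.alpha)

    def summary(self) -> str:
        n_sig_up = int(
            ((self.frame["direction_set"] == "up") & (self.frame["p_value"] < self.alpha)).sum()
        )
        n_sig_down = int(
            ((self.frame["direction_set"] == "down") & (self.frame["p_value"] < self.alpha)).sum()
        )
        lines = [
            "Kinase enrichment summary",
            "=" * 44,
            f"universe sites    : {len(self.model.universe)}",
            f"up / down sets    : {len(self.model.up_ids)} / {len(self.model.down_ids)}",
            f"kinases tested    : {len(self.model.kinases)}",
            f"cutoff FPR        : {self.model.fpr}",
            f"enriched (up set) : {n_sig_up} at p < {self.alpha}",
            f"enriched (down)   : {n_sig_down} at p < {self.alpha}",
        ]
        return "\n".join(lines)
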