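"""Ingestion and normalization of pathogenicity predictor scores.

Three machine-learning predictors contribute per-variant scores:

* an evolutionary-model score (EVE-style, with k-nearest-neighbour imputed
  values pooled in), raw range [0, 1], higher = more pathogenic;
* a protein-language-model masked-marginal log-odds (ESM-style), unbounded
  below, more negative = more deleterious;
* a molecular-feature functional-impact score (FIRM-style), raw range [0, 1],
  higher = more pathogenic.

Each model's raw scores are min-max normalized over the entire loaded dataset
so that 1 is the most deleterious; the language-model score is flipped
(``1 - norm(X)``) because its raw orientation is reversed. The per-variant
score matrix records, for variant ``i`` and model ``j``, the availability
indicator ``1_i^j``, the normalized score ``S_i^(j)`` and the model count
``M_i = sum_j 1_i^j``; variants with ``M_i < 2`` are ineligible for the
dataset-level ranking but stay in the dataset for family-level ranking.

Evolutionary-model lookups are matched by an 11-residue sequence window (the
variant residue plus five flanking residues each side, clipped at termini)
that must occur exactly once in the database protein sequence, guarding
against isoform numbering mismatches.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .cohort import Variant
from .errors import ConfigError, DataError, DegenerateRangeError

MODELS = ("EVE", "ESM", "FIRM")
#: raw-score orientation per model; "lower" means more negative = deleterious
ORIENTATION: dict[str, str] = {
    "EVE": "higher_is_pathogenic",
    "ESM": "lower_is_pathogenic",
    "FIRM": "higher_is_pathogenic",
}


@dataclass(frozen=True)
class EsmQuery:
    """A masked-position query against a protein language model."""
    sequence: str
    position_in_window: int  # 1-based
    wt_aa: str
    mut_aa: str
    logp_wt: float
    logp_mut: float

    def __post_init__(self) -> None:
        if not (1 <= self.position_in_window <= len(self.sequence)):
            raise DataError("masked position outside sequence bounds")
        if self.logp_wt > 0 or self.logp_mut > 0:
            raise DataError("log-probabilities must be <= 0")


@dataclass
class NormalizationStats:
    model: str
    min: float
    max: float
    n: int
    X_descriptor: str = "dataset"

    def to_dict(self) -> dict:
        return {"model": self.model, "min": self.min, "max": self.max,
                "n": self.n, "X_descriptor": self.X_descriptor}


@dataclass
class ScoreRecord:
    """Per-variant score matrix row: raw and normalized scores with
    availability indicators."""
    variant_id: str
    raw: dict[str, float] = field(default_factory=dict)
    S: dict[str, float] = field(default_factory=dict)
    eve_source: Literal["direct", "knn-imputed", "absent"] = "absent"

    @property
    def indicator(self) -> dict[str, int]:
        return {m: int(m in self.S) for m in MODELS}

    @property
    def M(self) -> int:
        return sum(self.indicator.values())

    @property
    def dsrank_eligible(self) -> bool:
        return self.M >= 2


@dataclass
class EveEntry:
    """Database entry for one protein: its sequence and the per-position,
    per-substitution scores with their source (direct vs knn-imputed)."""
    accession: str
    sequence: str
    scores: dict[tuple[int, str], float] = field(default_factory=dict)
    source: dict[tuple[int, str], str] = field(default_factory=dict)


def sequence_window(sequence: str, position: int, flank: int = 5) -> tuple[str, int]:
    """The variant residue with ``flank`` residues each side, clipped at the
    termini. Returns (window, 0-based offset of the variant within it)."""
    if not (1 <= position <= len(sequence)):
        raise DataError(f"position {position} outside sequence of length {len(sequence)}")
    lo = max(0, position - 1 - flank)
    hi = min(len(sequence), position + flank)
    return sequence[lo:hi], position - 1 - lo


def match_eve_record(
    variant: Variant,
    protein_sequence: str,
    entry: EveEntry,
    flank: int = 5,
    log: list[str] | None = None,
) -> tuple[float | None, str]:
    """Look up the evolutionary-model score for a variant by unique window
    match against the database sequence.

    Returns ``(raw_score, source)`` with source in {"direct", "knn-imputed",
    "absent"}; a zero or ambiguous (>1) window match yields an absent score
    and a log entry.
    """
    def _note(msg: str) -> tuple[None, str]:
        if log is not None:
            log.append(f"{variant.variant_id}: {msg}")
        return None, "absent"

    if protein_sequence[variant.position - 1] != variant.wt_aa:
        return _note(
            f"wt residue mismatch at {variant.position}: sequence has "
            f"{protein_sequence[variant.position - 1]}, variant says {variant.wt_aa}")
    window, offset = sequence_window(protein_sequence, variant.position, flank)
    starts = [i for i in range(len(entry.sequence) - len(window) + 1)
              if entry.sequence.startswith(window, i)]
    if not starts:
        return _note("window not found in database sequence")
    if len(starts) > 1:
        return _note(f"ambiguous window ({len(starts)} matches)")
    matched_pos = starts[0] + offset + 1  # back to 1-based
    key = (matched_pos, variant.mut_aa)
    if key not in entry.scores:
        return _note(f"no score for substitution at matched position {matched_pos}")
    return entry.scores[key], entry.source.get(key, "direct")


def esm_window(sequence: str, position: int, max_len: int = 1022) -> tuple[str, int]:
    """Window a long protein for a language model with a fixed input cap.

    Sequences at or under ``max_len`` pass through unchanged. Longer ones are
    cut to a ``max_len``-residue window centred on the variant, shifted to
    stay within the sequence; the returned 1-based index points at the same
    residue inside the window.
    """
    n = len(sequence)
    if not (1 <= position <= n):
        raise DataError(f"position {position} outside sequence of length {n}")
    if n <= max_len:
        return sequence, position
    start = position - 1 - max_len // 2
    start = min(max(start, 0), n - max_len)
    return sequence[start:start + max_len], position - start


def esm_masked_marginal(q: EsmQuery) -> float:
    """Masked-marginal log-odds: log P(mut | context) - log P(wt | context).

    More negative = more deleterious; unbounded below.
    """
    return q.logp_mut - q.logp_wt


def minmax_normalize(
    raw: Sequence[float],
    orientation: Literal["higher_is_pathogenic", "lower_is_pathogenic"],
    model: str = "",
    descriptor: str = "dataset",
) -> tuple[np.ndarray, NormalizationStats]:
    """Min-max normalize a model's raw scores over the dataset so 1 is the
    most deleterious; ``lower_is_pathogenic`` applies ``1 - norm(X)``."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateRangeError(
            f"need >= 2 distinct raw scores to normalize (model {model or '?'})")
    lo, hi = float(x.min()), float(x.max())
    normed = (x - lo) / (hi - lo)
    if orientation == "lower_is_pathogenic":
        normed = 1.0 - normed
    elif orientation != "higher_is_pathogenic":
        raise ConfigError(f"unknown orientation {orientation!r}")
    return normed, NormalizationStats(model=model, min=lo, max=hi, n=int(x.size),
                                      X_descriptor=descriptor)


def normalize_model_scores(
    raw_by_model: dict[str, dict[str, float]],
) -> tuple[dict[str, dict[str, float]], dict[str, NormalizationStats]]:
    """Normalize each model's raw scores over all variants that model scored."""
    S: dict[str, dict[str, float]] = {}
    stats_out: dict[str, NormalizationStats] = {}
    for model, scores in raw_by_model.items():
        if model not in MODELS:
            raise ConfigError(f"unknown model {model!r}; expected one of {MODELS}")
        if not scores:
            S[model] = {}
            continue
        vids = sorted(scores)
        normed, st = minmax_normalize([scores[v] for v in vids],
                                      ORIENTATION[model], model=model)
        S[model] = dict(zip(vids, normed.tolist()))
        stats_out[model] = st
    return S, stats_out


def assemble_score_matrix(
    variants: Iterable[Variant],
    normalized: dict[str, dict[str, float]],
    raw: dict[str, dict[str, float]] | None = None,
    eve_source: dict[str, str] | None = None,
) -> list[ScoreRecord]:
    """One ScoreRecord per variant; indicators and M follow from which models
    scored it. A score keyed to an unknown variant_id is a data error."""
    vids = {v.variant_id for v in variants}
    for model, scores in normalized.items():
        unknown = set(scores) - vids
        if unknown:
            raise DataError(f"{model} scores reference unknown variants: "
                            f"{sorted(unknown)[:5]}")
    records = []
    for v in sorted(vids):
        rec = ScoreRecord(variant_id=v)
        for model in MODELS:
            if v in normalized.get(model, {}):
                rec.S[model] = normalized[model][v]
                if raw and v in raw.get(model, {}):
                    rec.raw[model] = raw[model][v]
        if "EVE" in rec.S:
            rec.eve_source = (eve_source or {}).get(v, "direct")  # type: ignore[assignment]
        records.append(rec)
    return records


@dataclass
class PairCorrelation:
    model_a: str
    model_b: str
    r: float | None
    p: float | None
    n: int
    note: str = ""


def pairwise_model_correlation(records: list[ScoreRecord]) -> list[PairCorrelation]:
    """Pearson correlation (two-tailed p) between each model pair, computed
    on normalized scores of jointly scored variants."""
    out = []
    for i, a in enumerate(MODELS):
        for b in MODELS[i + 1:]:
            xs = [(r.S[a], r.S[b]) for r in records if a in r.S and b in r.S]
            if len(xs) < 3:
                out.append(PairCorrelation(a, b, None, None, len(xs),
                                           note="insufficient data (n < 3)"))
                continue
            xa, xb = zip(*xs)
            res = stats.pearsonr(xa, xb)
            out.append(PairCorrelation(a, b, float(res.statistic),
                                       float(res.pvalue), len(xs)))
    return out


@dataclass
class StratumComparison:
    model: str
    mean_low: float | None
    mean_high: float | None
    n_low: int
    n_high: int
    p: float | None
    test: str
    note: str = ""


def frequency_stratum_comparison(
    variants: Iterable[Variant],
    raw_by_model: dict[str, dict[str, float]],
    strata: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.01), (0.01, 0.02)),
    test: Literal["welch", "mannwhitney"] = "welch",
) -> list[StratumComparison]:
    """Compare raw-score means between two allele-frequency strata (lo, hi]
    per model; the rarity filter's rationale check."""
    af = {v.variant_id: v.pop_af for v in variants if v.pop_af is not None}

    def in_stratum(a: float, s: tuple[float, float]) -> bool:
        return s[0] < a <= s[1]

    out = []
    for model in MODELS:
        scores = raw_by_model.get(model, {})
        low = [s for vid, s in scores.items()
               if vid in af and in_stratum(af[vid], strata[0])]
        high = [s for vid, s in scores.items()
                if vid in af and in_stratum(af[vid], strata[1])]
        if not low or not high:
            out.append(StratumComparison(model, None, None, len(low), len(high),
                                         None, test, note="empty stratum"))
            continue
        if test == "welch":
            p = float(stats.ttest_ind(low, high, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(low, high, alternative="two-sided").pvalue)
        out.append(StratumComparison(model, float(np.mean(low)), float(np.mean(high)),
                                     len(low), len(high), p, test))
    return out


# ---------------------------------------------------------------------------
# File ingestion (TSV dialects)

def read_eve_table(scores_path: str | Path,
                   sequences_path: str | Path | None = None) -> dict[str, EveEntry]:
    """Read the evolutionary-model score TSV keyed by
    (protein_accession, position, mut_aa) with optional ``source`` column
    (direct / knn-imputed), plus an optional FASTA of database sequences
    for window matching."""
    entries: dict[str, EveEntry] = {}
    if sequences_path is not None:
        from Bio import SeqIO
        for rec in SeqIO.parse(str(sequences_path), "fasta"):
            entries[rec.id] = EveEntry(accession=rec.id, sequence=str(rec.seq))
    with open(scores_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_accession", "position", "mut_aa", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(f"EVE table must have columns {sorted(required)}")
        for row in reader:
            acc = row["protein_accession"]
            entry = entries.setdefault(acc, EveEntry(accession=acc, sequence=""))
            key = (int(row["position"]), row["mut_aa"])
            entry.scores[key] = float(row["score"])
            entry.source[key] = row.get("source") or "direct"
    return entries


def read_per_variant_scores(path: str | Path,
                            score_col: str = "score") -> dict[str, float]:
    """Read a TSV of (variant_id, score) — the precomputed-score dialect used
    for language-model and molecular-feature scores."""
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"variant_id", score_col} <= set(reader.fieldnames):
            raise ConfigError(f"score table must have columns variant_id, {score_col}")
        for row in reader:
            val = row[score_col].strip()
            if val:
                out[row["variant_id"]] = float(val)
    return out


def read_logprob_table(path: str | Path) -> dict[int, dict[str, float]]:
    """Read per-position log-probabilities (TSV: position, amino_acid, logp)
    for assembling masked-marginal queries."""
    out: dict[int, dict[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"position", "amino_acid", "logp"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(f"log-probability table must have columns {sorted(required)}")
        for row in reader:
            out.setdefault(int(row["position"]), {})[row["amino_acid"]] = float(row["logp"])
    return out
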