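"""Z-scored amino-acid-set predictors of optimal growth temperature.

Across a proteome collection each amino acid's genomic frequency is
standardized (mean 0, sd 1 over genomes, n-1 convention).  A predictor is
an amino-acid set S; its per-genome score is the sum of the member
z-scores, and sets are ranked by the Pearson correlation of the score with
OGT.  A fitted linear map turns scores into OGT predictions.

Exhaustive set search is exponential in the alphabet, so it is capped
(restricted alphabet / maximum set size); greedy forward selection is the
default for the full alphabet.  Ties are broken lexicographically.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import AAProfile
from .genetics import AA_CLASSES
from .wstats import CorrelationResult, ogt_correlation

log = logging.getLogger(__name__)


@dataclass
class ZScoreModel:
    """Fitted Z-score predictor: standardization constants, set, score->OGT map."""

    means: dict[str, float]
    sds: dict[str, float]
    amino_acid_set: tuple[str, ...]
    slope: float = 0.0
    intercept: float = 0.0
    r: float = 0.0

    def __post_init__(self) -> None:
        if not self.amino_acid_set:
            raise ValueError("amino-acid set must be nonempty")
        for a in self.amino_acid_set:
            if a not in self.sds or self.sds[a] <= 0:
                raise ValueError(f"set member {a} lacks a positive sd")

    def score(self, freqs: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        if isinstance(freqs, pd.DataFrame):
            z = (freqs - pd.Series(self.means)) / pd.Series(self.sds)
            return z[list(self.amino_acid_set)].sum(axis=1).to_numpy()
        return np.array(
            [sum((freqs[a] - self.means[a]) / self.sds[a] for a in self.amino_acid_set)]
        )

    def predict_ogt(self, freqs: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        return self.intercept + self.slope * self.score(freqs)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "format": "nucadapt-zscore-model",
                "means": self.means,
                "sds": self.sds,
                "set": list(self.amino_acid_set),
                "slope": self.slope,
                "intercept": self.intercept,
                "r": self.r,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ZScoreModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        if d.get("format") != "nucadapt-zscore-model":
            raise ValueError("not a z-score model file")
        return cls(
            means=d["means"],
            sds=d["sds"],
            amino_acid_set=tuple(d["set"]),
            slope=d["slope"],
            intercept=d["intercept"],
            r=d["r"],
        )


def profiles_to_matrix(profiles: Sequence[AAProfile], index: Sequence[str] | None = None) -> pd.DataFrame:
    """Genome x amino-acid frequency matrix from AAProfiles."""
    return pd.DataFrame([p.freqs for p in profiles], index=index)


def zscore_table(freq_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize each amino-acid column across genomes.

    Columns with zero variance are excluded (logged).  Returns
    (z-scores, means, sds) with the excluded columns absent.
    """
    if len(freq_matrix) < 3:
        raise ValueError("need at least 3 genomes to standardize")
    means = freq_matrix.mean(axis=0)
    sds = freq_matrix.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = list(freq_matrix.columns[~keep])
    if dropped:
        log.info("excluding constant amino acids from z-scores: %s", dropped)
    cols = freq_matrix.columns[keep]
    z = (freq_matrix[cols] - means[cols]) / sds[cols]
    return z, means[cols], sds[cols]


def predictor_score(zscores: pd.DataFrame, amino_acid_set: Sequence[str]) -> np.ndarray:
    """Per-genome score: sum of z-scores over the set."""
    missing = set(amino_acid_set) - set(zscores.columns)
    if missing:
        raise ValueError(f"set members not modelled: {sorted(missing)}")
    return zscores[list(amino_acid_set)].sum(axis=1).to_numpy()


def _fit_model(
    zscores: pd.DataFrame,
    means: pd.Series,
    sds: pd.Series,
    ogts: np.ndarray,
    subset: tuple[str, ...],
) -> ZScoreModel:
    score = predictor_score(zscores, subset)
    r = float(np.corrcoef(score, ogts)[0, 1])
    slope, intercept = np.polyfit(score, ogts, 1)
    return ZScoreModel(
        means=means.to_dict(),
        sds=sds.to_dict(),
        amino_acid_set=subset,
        slope=float(slope),
        intercept=float(intercept),
        r=r,
    )


def search_predictor(
    freq_matrix: pd.DataFrame,
    ogts: Sequence[float],
    max_set_size: int = 3,
    strategy: str = "greedy",
    alphabet: Sequence[str] | None = None,
) -> ZScoreModel:
    """Best amino-acid set by Pearson r of the summed z-score with OGT.

    ``strategy='exhaustive'`` enumerates all subsets of the (restricted)
    alphabet up to ``max_set_size``; ``'greedy'`` grows the set by forward
    selection.  Ties are broken by the lexicographically smaller set.
    """
    ogts = np.asarray(ogts, dtype=float)
    if np.ptp(ogts) == 0:
        raise ValueError("OGT vector is constant; predictor search undefined")
    z, means, sds = zscore_table(freq_matrix)
    letters = sorted(alphabet if alphabet is not None else z.columns)
    missing = set(letters) - set(z.columns)
    if missing:
        raise ValueError(f"alphabet letters without z-scores: {sorted(missing)}")
    zmat = z[letters].to_numpy()
    yc = ogts - ogts.mean()
    ynorm = np.sqrt((yc**2).sum())

    def r_of(cols: tuple[int, ...]) -> float:
        s = zmat[:, cols].sum(axis=1)
        sc = s - s.mean()
        denom = np.sqrt((sc**2).sum()) * ynorm
        return float((sc @ yc) / denom) if denom > 0 else -np.inf

    if strategy == "exhaustive":
        best: tuple[float, tuple[str, ...]] | None = None
        for size in range(1, max_set_size + 1):
            for combo in itertools.combinations(range(len(letters)), size):
                r = r_of(combo)
                names = tuple(letters[c] for c in combo)
                if best is None or r > best[0] or (r == best[0] and names < best[1]):
                    best = (r, names)
        assert best is not None
        return _fit_model(z, means, sds, ogts, best[1])
    if strategy != "greedy":
        raise ValueError("strategy must be 'greedy' or 'exhaustive'")
    chosen: list[int] = []
    best_r = -np.inf
    while len(chosen) < max_set_size:
        candidates = [
            (r_of(tuple(chosen + [c])), letters[c], c)
            for c in range(len(letters))
            if c not in chosen
        ]
        candidates.sort(key=lambda t: (-t[0], t[1]))
        r, _, c = candidates[0]
        if r <= best_r:
            break
        chosen.append(c)
        best_r = r
    if not chosen:
        raise ValueError("greedy selection found no improving amino acid")
    return _fit_model(z, means, sds, ogts, tuple(letters[c] for c in sorted(chosen)))


def class_trend_correlations(
    freq_matrix: pd.DataFrame,
    ogts: Sequence[float],
    dipeptide_class_matrix: pd.DataFrame | None = None,
) -> dict[str, CorrelationResult]:
    """OGT correlations of h/p/c class frequencies (and dipeptide classes).

    ``dipeptide_class_matrix``, when given, holds per-genome class-level
    dipeptide contrasts (columns like 'hp', 'cc'); each column is
    correlated with OGT alongside the three composition classes.
    """
    out: dict[str, CorrelationResult] = {}
    for cls, members in AA_CLASSES.items():
        present = [a for a in members if a in freq_matrix.columns]
        values = freq_matrix[present].sum(axis=1).to_numpy()
        out[cls[0]] = ogt_correlation(values, ogts)
    if dipeptide_class_matrix is not None:
        for col in dipeptide_class_matrix.columns:
            out[col] = ogt_correlation(
                dipeptide_class_matrix[col].to_numpy(), ogts
            )
    return out
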