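"""Distance-based mutual-information scoring of herb pairs.

The tendency of two herbs x and y to form a deliberate pair in a formula
corpus is scored from two signals:

* **Mutual information** of their presence across the m formulae.  The
  default form is the joint-weighted pointwise mutual information

      MI(x, y) = P(x, y) * log2( P(x, y) / (P(x) P(y)) )

  with the limit convention MI = 0 when P(x, y) = 0.  Large positive values
  mean the herbs co-occur far more often than chance.  The full 2x2
  presence/absence mutual information is available as ``mi_form="joint2x2"``
  (note it is also large under *anti*-correlation).

* **Between-herb-distance**: within formula i, d(x, y, i) = |b_ix - b_iy|,
  the absolute difference of relative listing positions; d-bar averages this
  over exactly the formulae where both herbs appear.  Herbs listed close
  together tend to belong to the same functional unit of the formula.

The combined score is S = MI / d-bar by default (``score_form="ratio"``):
strictly increasing in MI at fixed distance and strictly decreasing in
distance at fixed MI.  ``score_form="complement"`` gives S = MI * (1 - d-bar)
with the same monotonicity.  Pair independence is additionally tested with a
Pearson chi-square on the 2x2 presence/absence contingency table.

The model object follows the statsmodels convention::

    res = DMIM(corpus, min_cooccur=3).fit()
    print(res.summary())
    res.pairs            # ranked DataFrame, one row per scored pair
    net = res.to_network(top_n=100)
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from herbnet.corpus import FormulaCorpus, load_corpus, load_property_table, load_synonym_map, normalize_names

MI_FORMS = ("pmi", "joint2x2")
SCORE_FORMS = ("ratio", "complement")

PAIR_COLUMNS = [
    "rank", "herb_x", "herb_y", "n_x", "n_y", "n_xy",
    "p_x", "p_y", "p_xy", "mi", "d_bar", "score",
    "chi2", "p_value", "chi2_degenerate",
]


# -- per-pair primitives ---------------------------------------------------


def cooccurrence_counts(
    corpus: FormulaCorpus, x: int | str, y: int | str
) -> tuple[int, int, int, int]:
    """Occurrence counts (n_x, n_y, n_xy, m) of two herbs over all formulae."""
    cx, cy = corpus.column(x), corpus.column(y)
    if cx == cy:
        raise ValueError("x and y must be two distinct herbs")
    in_x = corpus.A[:, cx] > 0
    in_y = corpus.A[:, cy] > 0
    return int(in_x.sum()), int(in_y.sum()), int((in_x & in_y).sum()), corpus.m


def _mi_from_counts(n_x: int, n_y: int, n_xy: int, m: int, form: str = "pmi") -> float:
    if form == "pmi":
        if n_xy == 0:
            return 0.0
        p_x, p_y, p_xy = n_x / m, n_y / m, n_xy / m
        return p_xy * math.log2(p_xy / (p_x * p_y))
    if form == "joint2x2":
        # cells of the presence/absence table with their row/column margins
        cells = (
            (n_xy, n_x, n_y),
            (n_x - n_xy, n_x, m - n_y),
            (n_y - n_xy, m - n_x, n_y),
            (m - n_x - n_y + n_xy, m - n_x, m - n_y),
        )
        total = 0.0
        for c, r, s in cells:
            if c > 0:
                total += (c / m) * math.log2((c * m) / (r * s))
        return total
    raise ValueError(f"unknown mi_form {form!r}; expected one of {MI_FORMS}")


def mutual_information(
    corpus: FormulaCorpus, x: int | str, y: int | str, form: str = "pmi"
) -> float:
    """Mutual information (bits) of the presence of herbs x and y."""
    n_x, n_y, n_xy, m = cooccurrence_counts(corpus, x, y)
    if n_x == 0 or n_y == 0:
        raise ValueError("herb absent from every formula; MI undefined")
    return _mi_from_counts(n_x, n_y, n_xy, m, form)


def between_herb_distance(
    corpus: FormulaCorpus, x: int | str, y: int | str, i: int
) -> float:
    """|b_ix - b_iy| within formula i (0-based row index).

    Both herbs must be present; the result lies in [1/k_i, (k_i-1)/k_i].
    """
    cx, cy = corpus.column(x), corpus.column(y)
    if corpus.A[i, cx] == 0 or corpus.A[i, cy] == 0:
        raise ValueError(
            f"both herbs must be present in formula {corpus.formulae[i].formula_id!r}"
        )
    return float(abs(corpus.B[i, cx] - corpus.B[i, cy]))


def mean_distance(corpus: FormulaCorpus, x: int | str, y: int | str) -> float:
    """Mean between-herb-distance over the formulae where x and y co-occur."""
    cx, cy = corpus.column(x), corpus.column(y)
    mask = (corpus.A[:, cx] > 0) & (corpus.A[:, cy] > 0)
    if not mask.any():
        raise ValueError("herbs never co-occur; mean distance undefined")
    return float(np.abs(corpus.B[mask, cx] - corpus.B[mask, cy]).mean())


def _combine(mi: float, d_bar: float, score_form: str) -> float:
    if score_form == "ratio":
        return mi / d_bar
    if score_form == "complement":
        return mi * (1.0 - d_bar)
    raise ValueError(f"unknown score_form {score_form!r}; expected one of {SCORE_FORMS}")


def dmim_score(
    corpus: FormulaCorpus,
    x: int | str,
    y: int | str,
    mi_form: str = "pmi",
    score_form: str = "ratio",
    min_cooccur: int = 3,
) -> float:
    """Combined pair score; raises if the pair co-occurs fewer than
    ``min_cooccur`` times (such pairs are filtered, not scored)."""
    n_x, n_y, n_xy, m = cooccurrence_counts(corpus, x, y)
    if n_xy < min_cooccur:
        raise ValueError(
            f"pair co-occurs {n_xy} < min_cooccur={min_cooccur} times; filtered"
        )
    mi = _mi_from_counts(n_x, n_y, n_xy, m, mi_form)
    d_bar = mean_distance(corpus, x, y)
    return _combine(mi, d_bar, score_form)


class Chi2Result(NamedTuple):
    chi2: float
    p_value: float
    degenerate: bool = False


def pair_chi2(n_x: int, n_y: int, n_xy: int, m: int) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    presence/absence table of two herbs.

    A zero row or column margin leaves the test undefined: the result is
    then (0, 1) with ``degenerate=True`` and a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    a, b, c, d = n_xy, n_x - n_xy, n_y - n_xy, m - n_x - n_y + n_xy
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent counts n_x={n_x}, n_y={n_y}, n_xy={n_xy}, m={m}"
        )
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        warnings.warn(
            "degenerate 2x2 table (zero margin): chi-square undefined, p set to 1",
            stacklevel=2,
        )
        return Chi2Result(0.0, 1.0, True)
    chi2 = m * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return Chi2Result(float(chi2), float(stats.chi2.sf(chi2, 1)), False)


# -- corpus-wide ranking ---------------------------------------------------


def score_all_pairs(
    corpus: FormulaCorpus,
    min_cooccur: int = 3,
    mi_form: str = "pmi",
    score_form: str = "ratio",
) -> pd.DataFrame:
    """Score every unordered herb pair meeting the co-occurrence floor.

    Returns a DataFrame (columns :data:`PAIR_COLUMNS`) sorted by score
    descending; ties broken by smaller mean distance, then lexicographic
    herb names, so the ranking is deterministic.  ``df.attrs["n_filtered"]``
    counts pairs that co-occur at least once but below ``min_cooccur``.
    """
    if corpus.n < 2:
        raise ValueError("need at least two herbs to score pairs")
    _mi_from_counts(1, 1, 1, 1, mi_form)   # validate forms up front
    _combine(0.0, 0.5, score_form)
    X = corpus.A > 0
    m = corpus.m
    occ = X.sum(axis=0)
    N = X.T.astype(np.int64) @ X.astype(np.int64)
    names = corpus.herb_names
    rows = []
    n_filtered = 0
    for cx in range(corpus.n):
        col_x = X[:, cx]
        for cy in range(cx + 1, corpus.n):
            n_xy = int(N[cx, cy])
            if n_xy < min_cooccur:
                if n_xy > 0:
                    n_filtered += 1
                continue
            n_x, n_y = int(occ[cx]), int(occ[cy])
            mask = col_x & X[:, cy]
            d_bar = float(np.abs(corpus.B[mask, cx] - corpus.B[mask, cy]).mean())
            mi = _mi_from_counts(n_x, n_y, n_xy, m, mi_form)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi2, p_value, degenerate = pair_chi2(n_x, n_y, n_xy, m)
            rows.append({
                "herb_x": names[cx], "herb_y": names[cy],
                "n_x": n_x, "n_y": n_y, "n_xy": n_xy,
                "p_x": n_x / m, "p_y": n_y / m, "p_xy": n_xy / m,
                "mi": mi, "d_bar": d_bar,
                "score": _combine(mi, d_bar, score_form),
                "chi2": chi2, "p_value": p_value, "chi2_degenerate": degenerate,
            })
    df = pd.DataFrame(rows, columns=[c for c in PAIR_COLUMNS if c != "rank"])
    if len(df):
        df = df.sort_values(
            ["score", "d_bar", "herb_x", "herb_y"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.attrs["n_filtered"] = n_filtered
    df.attrs["config"] = {
        "min_cooccur": min_cooccur, "mi_form": mi_form, "score_form": score_form,
    }
    return df


# -- model / results objects ----------------------------------------------


class DMIM:
    """Distance-based mutual-information model over a formula corpus.

    Parameters
    ----------
    corpus : FormulaCorpus
        Encoded corpus (see :mod:`herbnet.corpus`).
    mi_form : {"pmi", "joint2x2"}
        Mutual-information functional form.
    score_form : {"ratio", "complement"}
        How MI and mean distance combine: MI/d-bar or MI*(1-d-bar).
    min_cooccur : int
        Minimum number of co-occurrences for a pair to be scored at all;
        rarer pairs are counted as filtered.
    """

    def __init__(
        self,
        corpus: FormulaCorpus,
        mi_form: str = "pmi",
        score_form: str = "ratio",
        min_cooccur: int = 3,
    ):
        if mi_form not in MI_FORMS:
            raise ValueError(f"mi_form must be one of {MI_FORMS}")
        if score_form not in SCORE_FORMS:
            raise ValueError(f"score_form must be one of {SCORE_FORMS}")
        if min_cooccur < 1:
            raise ValueError("min_cooccur must be >= 1")
        self.corpus = corpus
        self.mi_form = mi_form
        self.score_form = score_form
        self.min_cooccur = min_cooccur

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        synonyms: str | Path | None = None,
        properties: str | Path | None = None,
        dedupe: bool = False,
        **kwargs,
    ) -> "DMIM":
        """Convenience constructor: load, normalise and annotate a corpus."""
        corpus = load_corpus(corpus_path, dedupe=dedupe)
        if synonyms is not None:
            corpus = normalize_names(corpus, load_synonym_map(synonyms))
        if properties is not None:
            corpus = corpus.with_properties(load_property_table(properties))
        return cls(corpus, **kwargs)

    @property
    def config(self) -> dict:
        return {
            "mi_form": self.mi_form,
            "score_form": self.score_form,
            "min_cooccur": self.min_cooccur,
        }

    def fit(self) -> "DMIMResults":
        pairs = score_all_pairs(
            self.corpus, self.min_cooccur, self.mi_form, self.score_form
        )
        return DMIMResults(self, pairs, pairs.attrs["n_filtered"])


class DMIMResults:
    """Ranked pair scores plus network helpers for a fitted :class:`DMIM`."""

    def __init__(self, model: DMIM, pairs: pd.DataFrame, n_filtered: int):
        self.model = model
        self.pairs = pairs
        self.n_filtered = n_filtered

    @property
    def corpus(self) -> FormulaCorpus:
        return self.model.corpus

    @property
    def config(self) -> dict:
        return self.model.config

    def top_pairs(self, n: int = 20) -> pd.DataFrame:
        return self.pairs.head(n)

    def to_network(self, top_n: int = 100):
        from herbnet.network import build_network

        return build_network(
            self.pairs, top_n, properties=self.corpus.natural_properties()
        )

    def hub_module(self, hubs: Sequence[str], alpha: float = 0.05, fdr: bool = False):
        from herbnet.network import extract_hub_module

        return extract_hub_module(
            self.pairs, hubs, alpha=alpha,
            herb_names=self.corpus.herb_names, fdr=fdr,
        )

    def evaluate_recovery(self, reference_pairs, top_n: int = 100):
        from herbnet.network import evaluate_recovery

        return evaluate_recovery(self.to_network(top_n), reference_pairs)

    def summary(self, top: int = 10) -> str:
        c = self.corpus
        lines = [
            "Distance-based mutual-information pair ranking",
            "=" * 54,
            f"Formulae (m):        {c.m}",
            f"Herbs (n):           {c.n}",
            f"Pairs scored:        {len(self.pairs)}",
            f"Pairs filtered:      {self.n_filtered} "
            f"(co-occurring < {self.model.min_cooccur} times)",
            f"MI form:             {self.model.mi_form}",
            f"Score form:          {self.model.score_form}",
            "",
            f"Top {min(top, len(self.pairs))} pairs:",
        ]
        show = self.pairs.head(top)[
            ["rank", "herb_x", "herb_y", "n_xy", "mi", "d_bar", "score", "p_value"]
        ]
        lines.append(show.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        """Write the ranked pair table with a reproducibility header."""
        write_pairs(self.pairs, path, self.config)


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:12]


def write_pairs(pairs: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    config = config or pairs.attrs.get("config", {})
    with open(path, "w") as fh:
        fh.write(f"# herbnet pairs\t{json.dumps(config, sort_keys=True)}"
                 f"\tconfig_hash={config_hash(config)}\n")
        pairs.to_csv(fh, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a ranked pair table written by :func:`write_pairs`."""
    return pd.read_csv(path, sep="\t", comment="#")
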