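"""Author gender assignment from first-name probability tables.

First names map to a probability of being female; probabilities are
dichotomized at 0.5 (exact ties stay unknown, the only symmetric choice) and
the ordered pair of first- and last-author genders forms the author
combination factor FF / MM / FM / MF, with an explicit ``unknown`` category
whenever either gender cannot be determined.  First and last authorship are
treated purely as junior/senior labels; no hierarchy is inferred.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NameTable", "dichotomize", "combination", "assign_genders"]

UNKNOWN = "unknown"
COMBINATIONS = ("FF", "MM", "FM", "MF")


class NameTable:
    """Case-insensitive mapping name -> (probability female, count)."""

    def __init__(self, mapping: dict[str, tuple[float, int]]):
        self._table = {}
        for name, (p, count) in mapping.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0,1]")
            self._table[self._norm(name)] = (float(p), int(count))

    @staticmethod
    def _norm(name: str) -> str:
        return str(name).strip().casefold()

    @classmethod
    def from_csv(cls, path) -> "NameTable":
        df = pd.read_csv(path)
        return cls({r.name: (r.p_female, r.count)
                    for r in df.itertuples(index=False)})

    @classmethod
    def bundled(cls) -> "NameTable":
        """The synthetic table shipped with the package (~200 names)."""
        with resources.as_file(
            resources.files("trialpower") / "data" / "synthetic_names.csv"
        ) as p:
            return cls.from_csv(p)

    def to_csv(self, path) -> None:
        rows = [(n, p, c) for n, (p, c) in sorted(self._table.items())]
        pd.DataFrame(rows, columns=["name", "p_female", "count"]).to_csv(
            Path(path), index=False)

    def lookup(self, name):
        """Probability the name is female, or None when unknowable."""
        if name is None or (isinstance(name, float) and np.isnan(name)):
            return None
        key = self._norm(name)
        if not key:
            return None
        hit = self._table.get(key)
        return None if hit is None else hit[0]

    def __len__(self):
        return len(self._table)

    def __contains__(self, name):
        return self._norm(name) in self._table


def lookup_gender(name, table: NameTable):
    """Convenience wrapper: probability female or None (unknown)."""
    return table.lookup(name)


def dichotomize(probability_female, threshold: float = 0.5) -> str:
    """F if p > threshold, M if p < threshold, unknown on an exact tie."""
    if probability_female is None:
        return UNKNOWN
    p = float(probability_female)
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability outside [0,1]")
    if p > threshold:
        return "F"
    if p < threshold:
        return "M"
    return UNKNOWN


def combination(first_gender: str, last_gender: str) -> str:
    """Ordered pair of dichotomized genders; any unknown makes it unknown."""
    if UNKNOWN in (first_gender, last_gender):
        return UNKNOWN
    return first_gender + last_gender


def assign_genders(trials: pd.DataFrame, table: NameTable,
                   threshold: float = 0.5) -> pd.DataFrame:
    """Per-trial gender assignment table.

    Returns trial_id, first_gender, last_gender, combination for every row
    of the corpus (columns first_author_name / last_author_name).
    """
    def one(name):
        return dichotomize(table.lookup(name), threshold)

    first = trials["first_author_name"].map(one)
    last = trials["last_author_name"].map(one)
    combo = [combination(f, l) for f, l in zip(first, last)]
    return pd.DataFrame({
        "trial_id": trials["trial_id"].to_numpy(),
        "first_gender": first.to_numpy(),
        "last_gender": last.to_numpy(),
        "combination": combo,
    })
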