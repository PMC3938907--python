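"""Categorical panel data: schemes, panels, I/O, validation and recoding.

A :class:`CategoricalPanel` is a subjects × waves grid of category codes with
a :class:`CategoryScheme` describing the levels.  All downstream machinery
(marginal models, transition models, lasagne plots) consumes this container.

Missing values are represented by the module-level sentinel :data:`MISSING`,
never by a string.  Comparing the sentinel against a category label with
``==`` raises ``TypeError`` so that silent false negatives cannot occur; test
for missingness with ``value is MISSING``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "CategoryScheme",
    "CategoricalPanel",
    "read_panel",
    "write_panel",
    "restrict_complete_cases",
    "add_missing_category",
    "reclassify_monotone",
    "collapse_levels",
    "trajectory_table",
    "monotone_violations",
]

_MISSING_CODE = -1


class _MissingType:
    """Singleton sentinel for missing cells (reserved, distinct from levels)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __eq__(self, other):
        if other is self:
            return True
        raise TypeError(
            "MISSING cannot be compared with category labels using '=='; "
            "test with 'value is MISSING' instead"
        )

    def __hash__(self):
        return object.__hash__(self)

    def __reduce__(self):
        return (_MissingType, ())


MISSING = _MissingType()


@dataclass(frozen=True)
class CategoryScheme:
    """Named, ordered set of category levels.

    Parameters
    ----------
    name:
        Name of the categorical variable (e.g. ``"smoking status"``).
    levels:
        Ordered, unique category labels.  Between 2 and 8 levels are
        supported; for readable lasagne plots at most 4 substantive levels
        (plus an optional "missing" level) are recommended.
    monotone_absorbing_source:
        Optional label of a level that, once left, can never be re-entered
        (e.g. ``"never"`` for smoking: a never smoker who smokes can never be
        a never smoker again).  Drives structural-zero handling in transition
        models and the monotone recode.
    """

    name: str
    levels: tuple[str, ...]
    monotone_absorbing_source: str | None = None

    def __post_init__(self):
        levels = tuple(str(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) != len(set(levels)):
            raise ValueError(f"scheme levels must be unique, got {levels}")
        if not 2 <= len(levels) <= 8:
            raise ValueError(
                f"scheme must have between 2 and 8 levels, got {len(levels)}"
            )
        src = self.monotone_absorbing_source
        if src is not None and src not in levels:
            raise ValueError(
                f"monotone_absorbing_source {src!r} is not one of the levels"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def index(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise KeyError(f"{label!r} is not a level of scheme {self.name!r}")


@dataclass(frozen=True)
class CategoricalPanel:
    """Subjects × waves grid of category codes.

    ``codes`` stores integer level indices into ``scheme.levels``; missing
    cells hold ``-1``.  The label-facing API (``values``, ``trajectory``)
    translates codes to labels and the :data:`MISSING` sentinel.
    """

    subject_ids: tuple
    waves: tuple[int, ...]
    codes: np.ndarray
    scheme: CategoryScheme

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        waves = tuple(int(w) for w in self.waves)
        object.__setattr__(self, "waves", waves)
        codes = np.asarray(self.codes, dtype=np.int32)
        codes = np.atleast_2d(codes)
        object.__setattr__(self, "codes", codes)
        if sorted(waves) != list(waves) or len(set(waves)) != len(waves):
            raise ValueError(f"waves must be strictly increasing, got {waves}")
        if codes.shape != (len(self.subject_ids), len(waves)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(waves)} waves"
            )
        if codes.size and (codes.min() < _MISSING_CODE or codes.max() >= self.scheme.n_levels):
            raise ValueError("codes contain values outside the scheme's levels")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def regular_spacing(self) -> bool:
        """Whether waves are equally spaced (the models assume they are)."""
        d = np.diff(self.waves)
        return bool(len(d) == 0 or np.all(d == d[0]))

    @property
    def n_missing(self) -> int:
        return int((self.codes == _MISSING_CODE).sum())

    def wave_index(self, wave: int) -> int:
        try:
            return self.waves.index(int(wave))
        except ValueError:
            raise KeyError(f"wave {wave} not in panel waves {self.waves}")

    def trajectory(self, i: int) -> tuple:
        """Trajectory of subject ``i`` as labels / :data:`MISSING`."""
        return tuple(
            MISSING if c == _MISSING_CODE else self.scheme.levels[c]
            for c in self.codes[i]
        )

    def values(self) -> np.ndarray:
        """Object array of labels with :data:`MISSING` in missing cells."""
        out = np.empty(self.codes.shape, dtype=object)
        for j, lvl in enumerate(self.scheme.levels):
            out[self.codes == j] = lvl
        out[self.codes == _MISSING_CODE] = MISSING
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long DataFrame with columns subject, wave, category (NaN = missing)."""
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for j, w in enumerate(self.waves):
                c = self.codes[i, j]
                rows.append(
                    (sid, w, np.nan if c == _MISSING_CODE else self.scheme.levels[c])
                )
        return pd.DataFrame(rows, columns=["subject", "wave", "category"])


def _coerce_categories(
    raw: pd.Series, scheme: CategoryScheme, normalise: bool
) -> tuple[np.ndarray, int]:
    """Map raw category strings to level codes; return (codes, n_unparseable)."""
    lookup: dict[str, int] = {}
    for j, lvl in enumerate(scheme.levels):
        lookup[lvl] = j
        if normalise:
            lookup.setdefault(lvl.strip().casefold(), j)
    codes = np.full(len(raw), _MISSING_CODE, dtype=np.int32)
    n_bad = 0
    for k, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        s = str(v)
        if normalise:
            code = lookup.get(s, lookup.get(s.strip().casefold()))
        else:
            code = lookup.get(s)
        if code is None:
            if s.strip() == "":
                continue
            n_bad += 1
        else:
            codes[k] = code
    return codes, n_bad


def _parse_wave_column(name: str) -> int:
    s = name[1:] if name.startswith(("w", "W")) else name
    try:
        return int(s)
    except ValueError:
        raise ValueError(f"cannot parse wave index from column name {name!r}")


def read_panel(
    source: str | IO[str],
    layout: str,
    scheme: CategoryScheme,
    *,
    delimiter: str = ",",
    normalise: bool = False,
) -> CategoricalPanel:
    """Read a delimited-text panel in long or wide layout.

    Long layout needs columns ``subject,wave,category``; wide layout needs a
    ``subject`` column plus one column per wave named ``w<wave>`` (or the bare
    wave number).  Category strings that match no scheme level become missing,
    with one warning reporting the count.  With ``normalise=True`` matching is
    case- and surrounding-whitespace-insensitive.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(source, sep=delimiter, dtype=str)

    if layout == "long":
        required = {"subject", "wave", "category"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"long layout requires columns {sorted(required)}, got {list(df.columns)}"
            )
        try:
            df["wave"] = df["wave"].astype(int)
        except (TypeError, ValueError):
            bad = df.loc[~df["wave"].astype(str).str.fullmatch(r"-?\d+"), "wave"]
            raise ValueError(f"non-integer wave value {bad.iloc[0]!r}")
        dup = df.duplicated(subset=["subject", "wave"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (subject, wave) pair: ({first['subject']}, {first['wave']})"
            )
        subjects = tuple(pd.unique(df["subject"]))
        waves = tuple(sorted(df["wave"].unique()))
        codes_flat, n_bad = _coerce_categories(df["category"], scheme, normalise)
        codes = np.full((len(subjects), len(waves)), _MISSING_CODE, dtype=np.int32)
        srow = {s: i for i, s in enumerate(subjects)}
        wcol = {w: j for j, w in enumerate(waves)}
        for k in range(len(df)):
            codes[srow[df["subject"].iloc[k]], wcol[df["wave"].iloc[k]]] = codes_flat[k]
    else:
        if "subject" not in df.columns:
            raise ValueError("wide layout requires a 'subject' column")
        wave_cols = [c for c in df.columns if c != "subject"]
        waves_parsed = [_parse_wave_column(c) for c in wave_cols]
        order = np.argsort(waves_parsed)
        wave_cols = [wave_cols[i] for i in order]
        waves = tuple(waves_parsed[i] for i in order)
        if len(set(waves)) != len(waves):
            raise ValueError(f"duplicate wave columns parsed from {list(df.columns)}")
        dup = df.duplicated(subset=["subject"])
        if dup.any():
            first = df.loc[dup.idxmax(), "subject"]
            raise ValueError(f"duplicate subject {first!r} in wide layout")
        subjects = tuple(df["subject"])
        n_bad = 0
        cols = []
        for c in wave_cols:
            col_codes, bad = _coerce_categories(df[c], scheme, normalise)
            n_bad += bad
            cols.append(col_codes)
        codes = np.column_stack(cols)

    if n_bad:
        warnings.warn(
            f"{n_bad} category value(s) did not match any level of scheme "
            f"{scheme.name!r} and were coded as missing",
            stacklevel=2,
        )
    return CategoricalPanel(subjects, waves, codes, scheme)


def write_panel(
    panel: CategoricalPanel,
    target: str | IO[str],
    layout: str = "long",
    *,
    delimiter: str = ",",
) -> None:
    """Write a panel as delimited text; missing cells become empty fields."""
    labels = np.empty(panel.codes.shape, dtype=object)
    labels[:] = ""
    for j, lvl in enumerate(panel.scheme.levels):
        labels[panel.codes == j] = lvl
    if layout == "long":
        rows = []
        for i, sid in enumerate(panel.subject_ids):
            for j, w in enumerate(panel.waves):
                rows.append((sid, w, labels[i, j]))
        out = pd.DataFrame(rows, columns=["subject", "wave", "category"])
    elif layout == "wide":
        out = pd.DataFrame(labels, columns=[f"w{w}" for w in panel.waves])
        out.insert(0, "subject", list(panel.subject_ids))
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    out.to_csv(target, sep=delimiter, index=False)


def restrict_complete_cases(panel: CategoricalPanel) -> CategoricalPanel:
    """Keep only subjects observed at every wave (complete-case restriction)."""
    keep = ~(panel.codes == _MISSING_CODE).any(axis=1)
    if not keep.any():
        warnings.warn("complete-case restriction removed every subject", stacklevel=2)
    return replace(
        panel,
        subject_ids=tuple(s for s, k in zip(panel.subject_ids, keep) if k),
        codes=panel.codes[keep],
    )


def add_missing_category(panel: CategoricalPanel, label: str = "missing") -> CategoricalPanel:
    """Promote missingness to an explicit category with the given label."""
    if label in panel.scheme.levels:
        raise ValueError(f"label {label!r} collides with an existing level")
    scheme = replace(panel.scheme, levels=panel.scheme.levels + (label,))
    codes = panel.codes.copy()
    codes[codes == _MISSING_CODE] = scheme.n_levels - 1
    return replace(panel, scheme=scheme, codes=codes)


def monotone_violations(panel: CategoricalPanel) -> list[tuple]:
    """(subject_id, wave) pairs where the absorbing-source level re-appears
    after a different observed level (e.g. "never smoker" after smoking)."""
    src = panel.scheme.monotone_absorbing_source
    if src is None:
        raise ValueError("scheme has no monotone_absorbing_source")
    s = panel.scheme.index(src)
    out = []
    for i in range(panel.n_subjects):
        ever = False
        for j, c in enumerate(panel.codes[i]):
            if c == _MISSING_CODE:
                continue
            if c == s:
                if ever:
                    out.append((panel.subject_ids[i], panel.waves[j]))
            else:
                ever = True
    return out


def reclassify_monotone(panel: CategoricalPanel, relabel_to: str) -> CategoricalPanel:
    """Relabel impossible re-entries of the absorbing-source level.

    Every cell equal to ``monotone_absorbing_source`` that is preceded, at any
    earlier wave, by a different non-missing level is relabelled to
    ``relabel_to`` (e.g. "never" after smoking becomes "ex").  Missing cells
    are ignored when detecting prior ever-status.  The result satisfies the
    monotone invariant and the operation is idempotent.
    """
    src = panel.scheme.monotone_absorbing_source
    if src is None:
        raise ValueError("scheme has no monotone_absorbing_source set")
    if relabel_to not in panel.scheme.levels or relabel_to == src:
        raise ValueError(
            f"relabel_to must be a level different from {src!r}, got {relabel_to!r}"
        )
    s = panel.scheme.index(src)
    r = panel.scheme.index(relabel_to)
    codes = panel.codes.copy()
    for i in range(codes.shape[0]):
        ever = False
        for j in range(codes.shape[1]):
            c = codes[i, j]
            if c == _MISSING_CODE:
                continue
            if c == s and ever:
                codes[i, j] = r
            elif c != s:
                ever = True
    return replace(panel, codes=codes)


def collapse_levels(
    panel: CategoricalPanel, mapping: Mapping[str, str]
) -> CategoricalPanel:
    """Merge levels through an old-level → new-level mapping.

    The mapping must be total on the scheme's levels.  New levels appear in
    first-appearance order of the mapping's image over the old level order.
    """
    missing_keys = [l for l in panel.scheme.levels if l not in mapping]
    if missing_keys:
        raise ValueError(f"mapping is missing levels {missing_keys}")
    new_levels: list[str] = []
    for old in panel.scheme.levels:
        tgt = mapping[old]
        if tgt not in new_levels:
            new_levels.append(tgt)
    code_map = np.array(
        [new_levels.index(mapping[l]) for l in panel.scheme.levels], dtype=np.int32
    )
    codes = panel.codes.copy()
    obs = codes != _MISSING_CODE
    codes[obs] = code_map[codes[obs]]
    src = panel.scheme.monotone_absorbing_source
    new_src = None
    if src is not None:
        image = mapping[src]
        preimage = {l for l in panel.scheme.levels if mapping[l] == image}
        if preimage == {src}:
            new_src = image  # merge with another level would break the semantics
    scheme = CategoryScheme(panel.scheme.name, tuple(new_levels), new_src)
    return replace(panel, scheme=scheme, codes=codes)


def trajectory_table(panel: CategoricalPanel) -> list[tuple[tuple, int]]:
    """Distinct trajectories with subject counts, most frequent first.

    Trajectories are tuples of labels (with :data:`MISSING` for missing
    cells); counts sum to the number of subjects.  Ties in count are broken
    by trajectory code order, so the table is deterministic.
    """
    keys: dict[tuple, int] = {}
    for i in range(panel.n_subjects):
        key = tuple(int(c) for c in panel.codes[i])
        keys[key] = keys.get(key, 0) + 1
    ordered = sorted(keys.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for key, count in ordered:
        traj = tuple(
            MISSING if c == _MISSING_CODE else panel.scheme.levels[c] for c in key
        )
        out.append((traj, count))
    return out


def panel_from_values(
    values: Sequence[Sequence], waves: Iterable[int], scheme: CategoryScheme,
    subject_ids: Sequence | None = None,
) -> CategoricalPanel:
    """Build a panel from nested label sequences (:data:`MISSING` or None allowed).

    Convenience constructor used heavily in tests and examples.
    """
    values = list(values)
    codes = np.full((len(values), len(tuple(waves))), _MISSING_CODE, dtype=np.int32)
    waves = tuple(waves)
    for i, row in enumerate(values):
        for j, v in enumerate(row):
            if v is None or v is MISSING:
                continue
            codes[i, j] = scheme.index(v)
    if subject_ids is None:
        subject_ids = tuple(f"s{i}" for i in range(len(values)))
    return CategoricalPanel(tuple(subject_ids), waves, codes, scheme)
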