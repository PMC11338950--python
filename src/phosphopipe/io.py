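"""Tabular IO for the pipeline.

All quantitative tables are minimal named-column TSVs (one reporter-intensity
column per TMT channel, named by channel id), deliberately decoupled from any
particular search-engine export; a column-alias map lets MaxQuant-style headers
be ingested without renaming files. Missing intensities are empty cells or
"NA" and are parsed to NaN, never to 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, alphabetical one-letter order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: padding character for window positions beyond protein termini
PAD = "_"
WINDOW_LENGTH = 15
CENTER = WINDOW_LENGTH // 2  # 0-based index of the phosphosite in its window


class FormatError(ValueError):
    """A file violates the expected tabular format."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class SiteRecord:
    """One quantified phosphosite.

    ``site_id`` is ``<accession>_<residue><position>`` (1-based UniProt-style
    position), e.g. ``P12345_S42``, so that site tables from different stages
    join on a stable key.  ``window`` is the +/-7 flanking sequence (15-mer,
    site at the center, ``_``-padded at protein termini).
    """

    protein_accession: str
    position: int
    residue: str
    localization_probability: float
    window: str
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise FormatError(f"residue must be S/T/Y, got {self.residue!r}")
        if len(self.window) != WINDOW_LENGTH:
            raise FormatError(
                f"window must be {WINDOW_LENGTH} characters, got {len(self.window)}"
            )
        if self.window[CENTER] != self.residue:
            raise FormatError(
                f"window center {self.window[CENTER]!r} does not match residue "
                f"{self.residue!r}"
            )
        bad = set(self.window) - set(AMINO_ACIDS + PAD)
        if bad:
            raise FormatError(f"window contains invalid characters {sorted(bad)}")
        if not 0.0 <= self.localization_probability <= 1.0:
            raise FormatError(
                f"localization probability {self.localization_probability} not in [0,1]"
            )
        if self.position < 1:
            raise FormatError(f"position must be 1-based positive, got {self.position}")

    @property
    def site_id(self) -> str:
        return f"{self.protein_accession}_{self.residue}{self.position}"


@dataclass
class ProteinRecord:
    """One protein's per-channel reporter intensities."""

    protein_accession: str
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass
class StudyDesign:
    """The channel -> (group, replicate) map that drives all grouping."""

    channels: list[str]
    group_of: dict[str, str]
    replicate_of: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate channel ids in design")
        for ch in self.channels:
            if ch not in self.group_of or ch not in self.replicate_of:
                raise FormatError(f"channel {ch!r} has no group/replicate assignment")
        pairs = [(self.group_of[c], self.replicate_of[c]) for c in self.channels]
        if len(set(pairs)) != len(pairs):
            raise FormatError("duplicate (group, replicate) pair in design")

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance (channel) order."""
        seen: list[str] = []
        for ch in self.channels:
            g = self.group_of[ch]
            if g not in seen:
                seen.append(g)
        return seen

    def channels_for(self, group: str) -> list[str]:
        chans = [c for c in self.channels if self.group_of[c] == group]
        if not chans:
            raise KeyError(f"unknown group {group!r}")
        return chans


@dataclass
class GeneSet:
    """A named set of identifiers (one GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# site / protein tables
# ---------------------------------------------------------------------------

# canonical column -> accepted aliases (case-insensitive match on stripped name)
_SITE_ALIASES: dict[str, tuple[str, ...]] = {
    "protein_accession": ("protein_accession", "protein", "accession", "proteins"),
    "position": ("position", "positions within proteins"),
    "residue": ("residue", "amino_acid", "amino acid"),
    "localization_probability": (
        "localization_probability",
        "localization_prob",
        "localization prob",
    ),
    "window": ("window", "sequence_window", "sequence window"),
}


def _resolve_columns(
    header: list[str],
    aliases: dict[str, tuple[str, ...]],
    column_map: dict[str, str] | None,
) -> dict[str, str]:
    """Map canonical column names to actual file columns, or raise."""
    lower = {c.strip().lower(): c for c in header}
    resolved: dict[str, str] = {}
    for canonical, names in aliases.items():
        if column_map and canonical in column_map:
            names = (column_map[canonical],)
        for name in names:
            if name.lower() in lower:
                resolved[canonical] = lower[name.lower()]
                break
        else:
            raise FormatError(f"missing required column {canonical!r}")
    return resolved


def _parse_intensities(row: pd.Series, channels: list[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for ch in channels:
        v = row[ch]
        if pd.isna(v) or (isinstance(v, str) and v.strip() in ("", "NA", "NaN")):
            out[ch] = np.nan
        else:
            out[ch] = float(v)
    return out


def read_site_table(
    path,
    design: StudyDesign,
    column_map: dict[str, str] | None = None,
) -> list[SiteRecord]:
    """Read a phosphosite quantification TSV into :class:`SiteRecord` objects.

    Channel order is always taken from ``design``, never from the file's
    column order. Rows with unparseable numeric fields are skipped with a
    logged count; a missing required column or a duplicate site id is a
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), _SITE_ALIASES, column_map)
    for ch in design.channels:
        if ch not in df.columns:
            raise FormatError(f"missing intensity column for channel {ch!r}")

    records: list[SiteRecord] = []
    seen: set[str] = set()
    skipped = 0
    for idx, row in df.iterrows():
        try:
            rec = SiteRecord(
                protein_accession=str(row[cols["protein_accession"]]).strip(),
                position=int(float(row[cols["position"]])),
                residue=str(row[cols["residue"]]).strip(),
                localization_probability=float(row[cols["localization_probability"]]),
                window=str(row[cols["window"]]).strip(),
                intensities=_parse_intensities(row, design.channels),
            )
        except FormatError:
            raise
        except (ValueError, TypeError):
            skipped += 1
            continue
        if rec.site_id in seen:
            raise FormatError(f"duplicate site id {rec.site_id!r} at row {idx}")
        seen.add(rec.site_id)
        records.append(rec)
    if skipped:
        logger.warning("read_site_table: skipped %d unparseable rows", skipped)
    logger.info("read_site_table: %d sites from %s", len(records), path)
    return records


def write_site_table(records: list[SiteRecord], path, design: StudyDesign) -> None:
    rows = []
    for r in records:
        row: dict = {
            "protein_accession": r.protein_accession,
            "position": r.position,
            "residue": r.residue,
            "localization_probability": r.localization_probability,
            "window": r.window,
        }
        for ch in design.channels:
            row[ch] = r.intensities.get(ch, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_PROTEIN_ALIASES: dict[str, tuple[str, ...]] = {
    "protein_accession": ("protein_accession", "protein", "accession", "majority protein ids"),
}


def read_protein_table(
    path,
    design: StudyDesign,
    column_map: dict[str, str] | None = None,
) -> list[ProteinRecord]:
    """Read a protein quantification TSV; duplicate accessions are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), _PROTEIN_ALIASES, column_map)
    for ch in design.channels:
        if ch not in df.columns:
            raise FormatError(f"missing intensity column for channel {ch!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    skipped = 0
    for _, row in df.iterrows():
        acc = str(row[cols["protein_accession"]]).strip()
        if not acc:
            skipped += 1
            continue
        if acc in seen:
            raise FormatError(f"duplicate protein accession {acc!r}")
        seen.add(acc)
        try:
            records.append(
                ProteinRecord(acc, _parse_intensities(row, design.channels))
            )
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("read_protein_table: skipped %d unparseable rows", skipped)
    return records


def write_protein_table(records: list[ProteinRecord], path, design: StudyDesign) -> None:
    rows = []
    for r in records:
        row: dict = {"protein_accession": r.protein_accession}
        for ch in design.channels:
            row[ch] = r.intensities.get(ch, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


def read_design(path) -> StudyDesign:
    """Read a design TSV with columns channel, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("channel", "group", "replicate"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in design file")
    channels = [str(c) for c in df["channel"]]
    return StudyDesign(
        channels=channels,
        group_of={str(c): str(g) for c, g in zip(df["channel"], df["group"])},
        replicate_of={str(c): int(r) for c, r in zip(df["channel"], df["replicate"])},
    )


def write_design(design: StudyDesign, path) -> None:
    pd.DataFrame(
        {
            "channel": design.channels,
            "group": [design.group_of[c] for c in design.channels],
            "replicate": [design.replicate_of[c] for c in design.channels],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} has {len(fields)} fields, expected >= 3"
                )
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# kinase reference
# ---------------------------------------------------------------------------


def read_kinase_reference(path) -> list:
    """Read a kinase reference TSV (kinase, family, window[, residue_class]).

    Rows are grouped by kinase into :class:`~phosphopipe.kinase.KinaseSpec`
    objects; the residue class (serine/threonine vs tyrosine kinase) defaults
    to the class of the reference windows' center residues.
    """
    from .kinase import KinaseSpec  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("kinase", "family", "window"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in kinase reference")
    specs: list[KinaseSpec] = []
    for name, sub in df.groupby("kinase", sort=False):
        windows = [str(w) for w in sub["window"]]
        for w in windows:
            if len(w) != WINDOW_LENGTH:
                raise FormatError(
                    f"kinase {name!r}: window {w!r} has length {len(w)}, "
                    f"expected {WINDOW_LENGTH}"
                )
        families = sub["family"].unique()
        residue_class = None
        if "residue_class" in sub.columns:
            rc = sub["residue_class"].dropna().unique()
            if len(rc):
                residue_class = str(rc[0])
        specs.append(
            KinaseSpec(
                name=str(name),
                family=str(families[0]),
                reference_windows=windows,
                residue_class=residue_class,
            )
        )
    return specs


def write_kinase_reference(specs: list, path) -> None:
    rows = []
    for s in specs:
        for w in s.reference_windows:
            rows.append(
                {
                    "kinase": s.name,
                    "family": s.family,
                    "window": w,
                    "residue_class": s.residue_class,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# small JSON helpers (ground truth, summaries)
# ---------------------------------------------------------------------------


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
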