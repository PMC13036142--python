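"""Readers, writers and typed containers for every table the pipeline touches.

All downstream modules consume the validated containers defined here rather
than raw files. Tables are tab-separated with a header row; gene sets use the
standard GMT format. Gene and kinase symbols are matched case-insensitively
(uppercased on read), because proteomics accessions/symbols and kinome panel
names come from different sources with no shared capitalisation convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from kinoproteo.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: TMT 11-plex reporter channels in mass order.
TMT11_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N",
    "129C", "130N", "130C", "131N", "131C",
)

#: number of significant digits used when writing numeric output
OUTPUT_SIGFIGS = 6


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene/kinase symbol for cross-dataset matching."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class SampleDesign:
    """Ordered TMT channels with their dose-group assignment.

    Parameters
    ----------
    channels
        Reporter channel labels, in column order of the PSM table.
    groups
        Dose-group label per channel (parallel to ``channels``).
    doses
        Numeric dose in µM per channel (parallel to ``channels``).
    """

    channels: tuple[str, ...]
    groups: tuple[str, ...]
    doses: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.channels) == len(self.groups) == len(self.doses)):
            raise ValidationError("channels, groups and doses must be parallel")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        sizes = pd.Series(self.groups).value_counts()
        if len(sizes) < 2:
            raise ValidationError("design needs at least 2 groups")
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValidationError(f"groups with fewer than 2 samples: {small}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return tuple(seen)

    def channels_of(self, group: str) -> list[str]:
        return [c for c, g in zip(self.channels, self.groups) if g == group]

    def dose_of(self, group: str) -> float:
        for g, d in zip(self.groups, self.doses):
            if g == group:
                return d
        raise KeyError(group)

    @property
    def top_dose_group(self) -> str:
        return max(self.group_labels, key=self.dose_of)

    @classmethod
    def default_tmt11(cls) -> "SampleDesign":
        """The 11-plex, 4-dose design: vehicle/1/2.5/10 µM at n = 3,3,3,2."""
        groups = ("vehicle",) * 3 + ("1uM",) * 3 + ("2.5uM",) * 3 + ("10uM",) * 2
        doses = (0.0,) * 3 + (1.0,) * 3 + (2.5,) * 3 + (10.0,) * 2
        return cls(channels=TMT11_CHANNELS, groups=groups, doses=doses)

    @classmethod
    def from_table(cls, path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", dtype={"channel": str, "group": str})
        for col in ("channel", "group", "dose"):
            if col not in df.columns:
                raise FormatError(f"design table missing column '{col}'")
        return cls(
            channels=tuple(df["channel"]),
            groups=tuple(df["group"]),
            doses=tuple(float(d) for d in df["dose"]),
        )

    def to_table(self, path) -> None:
        pd.DataFrame(
            {"channel": self.channels, "group": self.groups, "dose": self.doses}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PsmTable:
    """PSM-level quantification: one row per peptide-spectrum match.

    ``frame`` columns: ``psm_id``, ``protein``, ``psm_fdr`` plus one intensity
    column per design channel. Intensities are non-negative; a zero means the
    reporter ion was not observed in that channel.
    """

    frame: pd.DataFrame
    design: SampleDesign

    def __post_init__(self):
        cols = set(self.frame.columns)
        missing = [c for c in ("psm_id", "protein", "psm_fdr") if c not in cols]
        missing += [c for c in self.design.channels if c not in cols]
        if missing:
            raise FormatError(f"PSM table missing columns: {missing}")
        inten = self.frame[list(self.design.channels)]
        neg = inten.lt(0).any(axis=1)
        if neg.any():
            rows = self.frame.index[neg].tolist()[:5]
            raise ValidationError(f"negative intensity at row(s) {rows}")
        bad_fdr = ~self.frame["psm_fdr"].between(0, 1)
        if bad_fdr.any():
            rows = self.frame.index[bad_fdr].tolist()[:5]
            raise ValidationError(f"psm_fdr outside [0,1] at row(s) {rows}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def intensities(self) -> pd.DataFrame:
        return self.frame[list(self.design.channels)]


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional per-gene pathway-position tag.

    ``positions`` maps gene symbol -> {'upstream','central','downstream'};
    genes without a tag default to 'central' downstream.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    positions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def position_of(self, gene: str) -> str:
        return self.positions.get(normalize_symbol(gene), "central")


@dataclass
class SubstrateMap:
    """Unique kinase -> substrate pairs (symbols normalized)."""

    pairs: pd.DataFrame  # columns: kinase, substrate

    def __post_init__(self):
        self.pairs = self.pairs.drop_duplicates(ignore_index=True)

    def substrates_of(self, kinase: str) -> set[str]:
        k = normalize_symbol(kinase)
        return set(self.pairs.loc[self.pairs["kinase"] == k, "substrate"])

    @property
    def kinases(self) -> list[str]:
        return sorted(self.pairs["kinase"].unique())


def read_psm_table(path, design: SampleDesign,
                   exclude_prefixes: tuple[str, ...] = ()) -> PsmTable:
    """Read a tab-separated PSM quantification table.

    ``exclude_prefixes`` optionally drops contaminant/decoy accessions (e.g.
    ``("rev_", "contam_")``); every exclusion is logged with its count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "protein": str},
                     comment="#")
    for ch in design.channels:
        if ch not in df.columns:
            raise FormatError(f"PSM table header lacks channel column '{ch}'")
    if exclude_prefixes:
        drop = df["protein"].str.startswith(tuple(exclude_prefixes))
        if drop.any():
            logger.info("excluding %d PSMs by accession prefix %s",
                        int(drop.sum()), exclude_prefixes)
        df = df[~drop].reset_index(drop=True)
    df["protein"] = df["protein"].map(normalize_symbol)
    return PsmTable(frame=df, design=design)


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            genes, seen = [], set()
            dups = []
            for g in fields[2:]:
                g = normalize_symbol(g)
                if not g:
                    continue
                if g in seen:
                    dups.append(g)
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning("GMT set '%s': deduplicated genes %s", name, dups)
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path,
                        description: str = "synthetic") -> None:
    """Write gene sets in GMT format (inverse of ``read_gene_sets_gmt``)."""
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_position_table(positions: dict[str, str], path) -> None:
    """Write a gene -> pathway-position table."""
    pd.DataFrame(sorted(positions.items()),
                 columns=["gene", "position"]).to_csv(path, sep="\t",
                                                      index=False)


def read_position_table(path) -> dict[str, str]:
    """Read a gene -> pathway-position (upstream/central/downstream) table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "position"):
        if col not in df.columns:
            raise FormatError(f"position table missing column '{col}'")
    bad = ~df["position"].isin(["upstream", "central", "downstream"])
    if bad.any():
        raise ValidationError(
            f"unknown position tag(s): {sorted(df.loc[bad, 'position'].unique())}")
    return {normalize_symbol(g): p for g, p in zip(df["gene"], df["position"])}


def read_kinome_panel(path) -> pd.DataFrame:
    """Read a kinome panel table (kinase, percent_control, pathway).

    Percent-control is the panel readout: 100 = uninhibited, 0 = complete
    inhibition. Duplicate kinase rows are returned as-is; deduplication (to
    the strongest inhibition) happens in kinome preprocessing.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kinase", "percent_control", "pathway"):
        if col not in df.columns:
            raise FormatError(f"kinome panel missing column '{col}'")
    bad = ~df["percent_control"].between(0, 100)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValidationError(
            f"percent_control outside [0,100] at row(s) {rows}")
    df = df.copy()
    df["kinase"] = df["kinase"].map(normalize_symbol)
    return df


def read_substrate_map(path) -> SubstrateMap:
    """Read a two-column kinase -> substrate TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kinase", "substrate"):
        if col not in df.columns:
            raise FormatError(f"substrate map missing column '{col}'")
    df = df.copy()
    df["kinase"] = df["kinase"].map(normalize_symbol)
    df["substrate"] = df["substrate"].map(normalize_symbol)
    return SubstrateMap(pairs=df[["kinase", "substrate"]])


def _format_value(v):
    if isinstance(v, float):
        return f"{v:.{OUTPUT_SIGFIGS}g}"
    return v


def write_results_table(records, path) -> None:
    """Write records (DataFrame or list of dicts) as a TSV.

    Column order is the schema order of the first record (deterministic);
    floats are rendered at 6 significant digits so the table round-trips
    through ``pandas.read_csv`` within formatting precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    df = df.map(_format_value)
    df.to_csv(path, sep="\t", index=False)
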