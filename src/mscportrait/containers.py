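"""Shared in-memory containers used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table (FPKM or read counts) with group labels.

    ``data`` is indexed by gene id with one column per sample; ``groups`` maps
    every sample id to its tissue group label (e.g. ``"BM"`` / ``"PL"``).
    """

    data: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        missing = [s for s in self.data.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.data.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.groups.values()):
            raise KeyError(f"unknown group label: {group!r}")
        return [s for s in self.data.columns if self.groups[s] == group]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "group_row", "")
        # first data row carries the group labels so the file round-trips
        header = pd.DataFrame(
            [[""] + [self.groups[s] for s in self.data.columns]],
            columns=["group_row"] + list(self.data.columns),
            index=pd.Index(["#group"], name=self.data.index.name),
        )
        pd.concat([header, out]).drop(columns="group_row").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        groups = raw.loc["#group"].to_dict()
        data = raw.drop(index="#group").astype(float)
        return cls(data=data, groups=groups)


@dataclass
class GeneSet:
    """Named collection of gene ids with an optional source tag."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __init__(self, name: str, members, source: str = ""):
        self.name = name
        self.members = frozenset(members)
        self.source = source

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GroundTruth:
    """Planted signal recorded by the synthetic generators."""

    expressed_gene_ids: frozenset[str] = field(default_factory=frozenset)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2fc
    tf_ids: tuple[str, ...] = ()
    regulator_tf_ids: tuple[str, ...] = ()
    planted_sites: pd.DataFrame | None = None  # gene, tf, offset, strand
    hypomethylated_gene_ids: frozenset[str] = field(default_factory=frozenset)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, source, *members = line.split("\t")
            sets.append(GeneSet(name=name, members=members, source=source))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.members)]) + "\n")


def rng_from_seed(seed) -> np.random.Generator:
    return np.random.default_rng(seed)
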