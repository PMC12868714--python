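"""Hybrid-guide (hgRNA) library manifests.

An hgRNA is a single transcript fusing a Cas9 spacer and a Cas12a spacer;
each library record defines one combinatorial perturbation identity. Target
classes follow the screen design: exon deletions (guide pairs cutting the
flanking introns), gene knockouts (both nucleases mutating the gene),
intergenic cutting controls and non-targeting controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TARGET_CLASSES = ("exon_deletion", "gene_knockout", "intergenic", "non_targeting")
CONTROL_CLASSES = ("intergenic", "non_targeting")

CAS9_SPACER_LEN = 20
CAS12A_SPACER_LEN = 23

_MANIFEST_COLUMNS = [
    "hgrna_id",
    "cas9_spacer",
    "cas12a_spacer",
    "target_class",
    "target_id",
    "guide_index",
]


@dataclass(frozen=True)
class GuideRecord:
    hgrna_id: str
    cas9_spacer: str
    cas12a_spacer: str
    target_class: str
    target_id: str
    guide_index: int


@dataclass
class GuideLibrary:
    """Manifest of hgRNAs with spacer pairs, target class and target identity.

    Invariants enforced on construction: unique ``hgrna_id``; ``guide_index``
    1..k without gaps within each target; control records (intergenic /
    non-targeting) have ``target_id`` equal to their own ``hgrna_id``.
    """

    records: list[GuideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.hgrna_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("hgrna_id values must be unique")
        by_target: dict[str, list[int]] = {}
        for r in self.records:
            if r.target_class not in TARGET_CLASSES:
                raise ValueError(f"unknown target_class {r.target_class!r}")
            if r.target_class in CONTROL_CLASSES and r.target_id != r.hgrna_id:
                raise ValueError(
                    f"control record {r.hgrna_id} must have target_id == hgrna_id"
                )
            by_target.setdefault(r.target_id, []).append(r.guide_index)
        for target_id, idx in by_target.items():
            if sorted(idx) != list(range(1, len(idx) + 1)):
                raise ValueError(
                    f"guide_index for target {target_id} must be 1..k without gaps"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def hgrna_ids(self) -> list[str]:
        return [r.hgrna_id for r in self.records]

    def record(self, hgrna_id: str) -> GuideRecord:
        for r in self.records:
            if r.hgrna_id == hgrna_id:
                return r
        raise KeyError(hgrna_id)

    def target_of(self, hgrna_id: str) -> str:
        return self.record(hgrna_id).target_id

    def targets(self, target_class: str | None = None) -> list[str]:
        """Unique target ids, in library order, optionally of one class."""
        seen: dict[str, None] = {}
        for r in self.records:
            if target_class is None or r.target_class == target_class:
                seen.setdefault(r.target_id)
        return list(seen)

    def guides_of(self, target_id: str) -> list[str]:
        return [r.hgrna_id for r in self.records if r.target_id == target_id]

    def class_of_target(self, target_id: str) -> str:
        for r in self.records:
            if r.target_id == target_id:
                return r.target_class
        raise KeyError(target_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.hgrna_id, r.cas9_spacer, r.cas12a_spacer, r.target_class,
                 r.target_id, r.guide_index)
                for r in self.records
            ],
            columns=_MANIFEST_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GuideLibrary":
        missing = set(_MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        recs = [
            GuideRecord(
                str(row.hgrna_id), str(row.cas9_spacer), str(row.cas12a_spacer),
                str(row.target_class), str(row.target_id), int(row.guide_index),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(recs)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GuideLibrary":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def _random_spacers(rng: np.random.Generator, n: int, length: int,
                    taken: set[str]) -> list[str]:
    """Unique random nucleotide strings not colliding with ``taken``."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        s = "".join(bases[rng.integers(0, 4, size=length)])
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def simulate_guide_library(
    n_exon_targets: int,
    guides_per_exon: int = 3,
    n_gene_targets: int = 0,
    guides_per_gene: int = 2,
    n_intergenic: int = 40,
    n_nontargeting: int = 40,
    seed: int = 0,
) -> GuideLibrary:
    """Draw a synthetic hgRNA library mirroring the screen design.

    By default each exon target gets three independent guide pairs and each
    gene knockout two, plus 40 intergenic and 40 non-targeting control
    hgRNAs. Spacers are unique random nucleotide strings (20 nt Cas9,
    23 nt Cas12a). Deterministic in ``seed``.
    """
    counts = dict(
        n_exon_targets=n_exon_targets, guides_per_exon=guides_per_exon,
        n_gene_targets=n_gene_targets, guides_per_gene=guides_per_gene,
        n_intergenic=n_intergenic, n_nontargeting=n_nontargeting,
    )
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    rng = np.random.default_rng(seed)
    n_total = (n_exon_targets * guides_per_exon + n_gene_targets * guides_per_gene
               + n_intergenic + n_nontargeting)
    taken: set[str] = set()
    cas9 = _random_spacers(rng, n_total, CAS9_SPACER_LEN, taken)
    cas12a = _random_spacers(rng, n_total, CAS12A_SPACER_LEN, taken)

    records: list[GuideRecord] = []
    k = 0
    for t in range(n_exon_targets):
        target = f"EXON{t + 1:04d}"
        for g in range(1, guides_per_exon + 1):
            records.append(GuideRecord(f"{target}_g{g}", cas9[k], cas12a[k],
                                       "exon_deletion", target, g))
            k += 1
    for t in range(n_gene_targets):
        target = f"KO{t + 1:04d}"
        for g in range(1, guides_per_gene + 1):
            records.append(GuideRecord(f"{target}_g{g}", cas9[k], cas12a[k],
                                       "gene_knockout", target, g))
            k += 1
    for t in range(n_intergenic):
        hid = f"ITGC{t + 1:04d}"
        records.append(GuideRecord(hid, cas9[k], cas12a[k], "intergenic", hid, 1))
        k += 1
    for t in range(n_nontargeting):
        hid = f"NTGT{t + 1:04d}"
        records.append(GuideRecord(hid, cas9[k], cas12a[k], "non_targeting", hid, 1))
        k += 1
    return GuideLibrary(records)
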