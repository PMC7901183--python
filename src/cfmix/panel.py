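"""SNP capture panel: region model, synthetic panel generation, BED + sidecar I/O.

The panel targets short regions (~100 bp) on the 22 autosomes, each carrying a
single common biallelic SNP near the 3' end, plus SNP-free dosage regions on the
homologous ZFX/ZFY genes used to quantify sex-chromosome copy number. The
default layout mirrors an aneuploidy-focused design: 739 regions in total, with
dense tiling of chr13/18/21 (222/221/194 regions), 42 further autosomal regions
spread over the remaining autosomes, and 30 regions on each of ZFX and ZFY.

Coordinates are 0-based half-open (BED convention) at every interface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PanelRegion",
    "Panel",
    "PanelSpec",
    "default_panel_spec",
    "generate_panel",
    "write_panel",
    "read_panel",
]

AUTOSOMES = tuple(str(c) for c in range(1, 23))
SEX_DOSAGE_CHROMS = ("ZFX", "ZFY")

#: minimum distance of the panel SNP from the region 5' end, i.e. the SNP sits
#: within the last 30 bp of the region
SNP_WINDOW = 30

_BASES = np.array(list("ACGT"))


def _chrom_key(chrom: str) -> tuple[int, int]:
    if chrom in AUTOSOMES:
        return (0, int(chrom))
    if chrom == "ZFX":
        return (1, 0)
    if chrom == "ZFY":
        return (1, 1)
    raise ValueError(f"unknown chromosome label: {chrom!r}")


@dataclass(frozen=True)
class PanelRegion:
    """A single captured region; autosomal regions carry one biallelic SNP."""

    region_id: str
    chrom: str
    start: int
    end: int
    snp_offset: int | None = None
    ref: str | None = None
    alt: str | None = None
    pop_af: float | None = None

    def __post_init__(self) -> None:
        _chrom_key(self.chrom)  # validates the label
        if self.end <= self.start:
            raise ValueError(
                f"region {self.region_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.length < 40:
            raise ValueError(f"region {self.region_id}: length {self.length} < 40")
        if self.is_autosomal:
            if self.pop_af is None or not (0.0 < self.pop_af < 1.0):
                raise ValueError(
                    f"region {self.region_id}: autosomal pop_af must lie in (0,1), got {self.pop_af}"
                )
            if self.snp_offset is None or not (
                self.length - SNP_WINDOW <= self.snp_offset < self.length
            ):
                raise ValueError(
                    f"region {self.region_id}: snp_offset {self.snp_offset} not within "
                    f"the last {SNP_WINDOW} bp of a {self.length} bp region"
                )
            if self.ref == self.alt or self.ref is None or self.alt is None:
                raise ValueError(f"region {self.region_id}: ref/alt alleles must differ")
        else:
            if self.pop_af is not None or self.snp_offset is not None:
                raise ValueError(
                    f"region {self.region_id}: {self.chrom} dosage regions carry no SNP"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES


@dataclass(frozen=True)
class Panel:
    """Ordered collection of panel regions, sorted by (chromosome, start)."""

    regions: tuple[PanelRegion, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region_ids: {dupes[:5]}")
        ordered = sorted(
            self.regions, key=lambda r: (_chrom_key(r.chrom), r.start)
        )
        object.__setattr__(self, "regions", tuple(ordered))

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def autosomal(self) -> tuple[PanelRegion, ...]:
        return tuple(r for r in self.regions if r.is_autosomal)

    @property
    def zfx(self) -> tuple[PanelRegion, ...]:
        return tuple(r for r in self.regions if r.chrom == "ZFX")

    @property
    def zfy(self) -> tuple[PanelRegion, ...]:
        return tuple(r for r in self.regions if r.chrom == "ZFY")

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.regions:
            out[r.chrom] = out.get(r.chrom, 0) + 1
        return out

    @property
    def snp_ids(self) -> list[str]:
        return [r.region_id for r in self.autosomal]

    @property
    def pop_af(self) -> pd.Series:
        """Population alt-allele frequency per autosomal region, indexed by id."""
        return pd.Series(
            {r.region_id: r.pop_af for r in self.autosomal}, name="pop_af", dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.regions])


def _default_autosome_counts() -> dict[str, int]:
    counts = {"13": 222, "18": 221, "21": 194}
    # 42 background regions spread round-robin over the other 19 autosomes
    others = [c for c in AUTOSOMES if c not in counts]
    for i in range(42):
        c = others[i % len(others)]
        counts[c] = counts.get(c, 0) + 1
    return counts


@dataclass(frozen=True)
class PanelSpec:
    """Per-chromosome region counts plus the distributions used for synthesis.

    ``af_range`` bounds the Uniform population alt-allele frequency of the
    panel SNPs; mixture-informative panels select common variants, hence the
    default (0.2, 0.5). ``length_range`` gives Uniform region lengths with
    mean 100 bp.
    """

    autosome_counts: Mapping[str, int] = field(default_factory=_default_autosome_counts)
    n_zfx: int = 30
    n_zfy: int = 30
    af_range: tuple[float, float] = (0.2, 0.5)
    length_range: tuple[int, int] = (60, 140)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.autosome_counts.values()) or min(self.n_zfx, self.n_zfy) < 0:
            raise ValueError("region counts must be nonnegative")
        lo, hi = self.af_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("af_range must satisfy 0 < low < high < 1")
        if self.length_range[0] < 40:
            raise ValueError("minimum region length is 40 bp")


def default_panel_spec() -> PanelSpec:
    return PanelSpec()


def generate_panel(spec: PanelSpec | None = None, seed: int = 0) -> Panel:
    """Synthesize a panel satisfying the layout in ``spec``, deterministically.

    The same seed yields a bit-identical panel; different seeds change only
    coordinates, alleles and allele frequencies, never the per-chromosome
    counts.
    """
    spec = spec or default_panel_spec()
    n_auto = sum(spec.autosome_counts.values())
    if n_auto == 0:
        raise ValueError("panel must contain at least one autosomal SNP region")
    rng = np.random.default_rng(seed)
    lo_len, hi_len = spec.length_range
    lo_af, hi_af = spec.af_range

    regions: list[PanelRegion] = []
    chroms = sorted(spec.autosome_counts, key=_chrom_key) + [
        c for c, n in (("ZFX", spec.n_zfx), ("ZFY", spec.n_zfy)) if n > 0
    ]
    counts = dict(spec.autosome_counts)
    counts["ZFX"], counts["ZFY"] = spec.n_zfx, spec.n_zfy
    for chrom in chroms:
        n = counts[chrom]
        if n == 0:
            continue
        lengths = rng.integers(lo_len, hi_len + 1, size=n)
        gaps = rng.integers(5_000, 50_000, size=n)
        starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lengths[:-1])))
        ends = starts + lengths
        is_auto = chrom in AUTOSOMES
        if is_auto:
            offsets = lengths - 1 - rng.integers(0, SNP_WINDOW, size=n)
            afs = rng.uniform(lo_af, hi_af, size=n)
            refs = rng.integers(0, 4, size=n)
            alts = (refs + rng.integers(1, 4, size=n)) % 4
        for i in range(n):
            rid = f"{chrom}_{i + 1:04d}" if is_auto else f"{chrom}_{i + 1:02d}"
            if is_auto:
                regions.append(
                    PanelRegion(
                        region_id=rid,
                        chrom=chrom,
                        start=int(starts[i]),
                        end=int(ends[i]),
                        snp_offset=int(offsets[i]),
                        ref=str(_BASES[refs[i]]),
                        alt=str(_BASES[alts[i]]),
                        pop_af=float(afs[i]),
                    )
                )
            else:
                regions.append(
                    PanelRegion(rid, chrom, int(starts[i]), int(ends[i]))
                )
    return Panel(tuple(regions))


# ---------------------------------------------------------------------------
# serialization: 4-column BED + sidecar TSV of SNP annotations

SIDECAR_COLUMNS = ["region_id", "ref", "alt", "snp_offset", "pop_af"]


def _sidecar_path(bed_path: Path) -> Path:
    return bed_path.with_suffix(".snps.tsv")


def write_panel(panel: Panel, bed_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write ``panel`` as a headerless 4-column BED plus a SNP sidecar TSV.

    The sidecar holds one row per autosomal region (``region_id ref alt
    snp_offset pop_af``); ZFX/ZFY dosage regions appear only in the BED.
    """
    bed_path = Path(bed_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(bed_path)
    with open(bed_path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")
    with open(sidecar_path, "w") as fh:
        fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
        for r in panel.autosomal:
            fh.write(f"{r.region_id}\t{r.ref}\t{r.alt}\t{r.snp_offset}\t{r.pop_af!r}\n")


def read_panel(bed_path: str | Path, sidecar_path: str | Path | None = None) -> Panel:
    """Read a panel written by :func:`write_panel`; round-trips bit-exactly."""
    bed_path = Path(bed_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(bed_path)

    snp: dict[str, dict] = {}
    with open(sidecar_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SIDECAR_COLUMNS:
            raise ValueError(f"{sidecar_path}:1: expected header {SIDECAR_COLUMNS}, got {header}")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{sidecar_path}:{ln}: expected 5 fields, got {len(parts)}")
            rid, ref, alt, off, af = parts
            if rid in snp:
                raise ValueError(f"{sidecar_path}:{ln}: duplicate region_id {rid!r}")
            af_f = float(af)
            if not (0.0 < af_f < 1.0):
                raise ValueError(f"{sidecar_path}:{ln}: pop_af {af} outside (0,1)")
            snp[rid] = {"ref": ref, "alt": alt, "snp_offset": int(off), "pop_af": af_f}

    regions: list[PanelRegion] = []
    seen: set[str] = set()
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{bed_path}:{ln}: expected 4 BED fields, got {len(parts)}")
            chrom, start_s, end_s, rid = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{ln}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{bed_path}:{ln}: end ({end}) <= start ({start})")
            if rid in seen:
                raise ValueError(f"{bed_path}:{ln}: duplicate region_id {rid!r}")
            seen.add(rid)
            ann = snp.get(rid)
            if chrom in AUTOSOMES and ann is None:
                raise ValueError(f"{bed_path}:{ln}: autosomal region {rid!r} missing from sidecar")
            try:
                regions.append(
                    PanelRegion(rid, chrom, start, end, **(ann or {}))
                )
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{ln}: {exc}") from exc
    extra = set(snp) - seen
    if extra:
        raise ValueError(f"{sidecar_path}: sidecar rows with no BED region: {sorted(extra)[:5]}")
    return Panel(tuple(regions))
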