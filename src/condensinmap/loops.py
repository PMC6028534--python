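"""Loop-spacing calculus for Condensins on mitotic chromosomes.

Converts chromosome-bound subunit totals, the genome model of the cell
line, and measured total chromatid-axis lengths into per-chromatid
counts, genomic and physical Condensin spacing, kleisin-limited
holocomplex numbers, Condensin I:II isoform ratios, and hierarchical
loop sizes under the loop-extrusion counting assumption (one holocomplex
per loop base, equidistant spacing along chromatid arms).

Units: genome sizes in bp (reported spacings in kb), axis lengths in µm
(reported physical spacings in nm), counts in molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

SUBUNITS = ("SMC4", "CAP-D2", "CAP-H", "CAP-D3", "CAP-H2")
#: combined kleisin pool (Condensin I + II holocomplex indicator)
COMBINED_KLEISIN = "CAP-H + CAP-H2"


@dataclass(frozen=True)
class GenomeModel:
    """Karyotype model of the imaged cell line.

    Defaults describe the hypotriploid HeLa Kyoto karyotype: a mean
    genome size of 7.9 Gb distributed over ~64 chromosomes.  During
    mitosis the genome is replicated, so a cell carries 2x the genome
    over 2x the chromosome number of sister chromatids.
    """

    genome_size_bp: float = 7.9e9
    n_chromosomes: int = 64
    replicated: bool = True

    @property
    def total_dna_bp(self) -> float:
        """Total DNA content of the mitotic cell (bp)."""
        return (2 if self.replicated else 1) * self.genome_size_bp

    @property
    def n_chromatids(self) -> int:
        return (2 if self.replicated else 1) * self.n_chromosomes

    @property
    def chromatid_genomic_length_bp(self) -> float:
        """Genomic length of an average chromatid (= genome/chromosomes)."""
        return self.total_dna_bp / self.n_chromatids


@dataclass
class CondensinCensus:
    """Chromosome-bound subunit totals for one mitotic phase."""

    phase: str
    totals: dict[str, float]
    total_axis_length_um: float
    totals_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.totals.items():
            if value <= 0:
                raise ValueError(f"census total for {name} must be > 0, got {value}")
        if self.total_axis_length_um <= 0:
            raise ValueError("total_axis_length_um must be > 0")

    @property
    def combined_kleisin_total(self) -> float:
        return self.totals["CAP-H"] + self.totals["CAP-H2"]


def load_packaged_census(phase: str) -> CondensinCensus:
    """Load the packaged per-phase census (live-cell measurement fixture)."""
    with resources.files("condensinmap.data").joinpath("table1.json").open() as fh:
        payload = json.load(fh)
    try:
        entry = payload["phases"][phase]
    except KeyError as exc:
        raise KeyError(f"unknown phase {phase!r}; choose from {list(payload['phases'])}") from exc
    return CondensinCensus(
        phase=phase,
        totals=dict(entry["totals"]),
        totals_sd=dict(entry["totals_sd"]),
        total_axis_length_um=entry["total_axis_length_um"],
    )


def load_packaged_genome_model() -> GenomeModel:
    with resources.files("condensinmap.data").joinpath("table1.json").open() as fh:
        payload = json.load(fh)
    g = payload["genome"]
    return GenomeModel(
        genome_size_bp=g["genome_size_bp"],
        n_chromosomes=g["n_chromosomes"],
        replicated=g["replicated"],
    )


def build_loop_table(census: CondensinCensus, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Per-subunit spacing table for one mitotic phase.

    For each subunit pool (the five measured subunits plus the combined
    kleisin pool) the table gives, assuming equidistant spacing of the
    pool along all chromatid arms:

    - ``per_chromatid``: molecules on an average chromatid
    - ``per_um``: molecules per µm of chromatid axis
    - ``per_Mb``: molecules per Mb of genomic DNA
    - ``genomic_spacing_kb``: mean genomic distance between neighbours
    - ``physical_spacing_nm``: mean axial distance between neighbours

    Under the loop-extrusion counting assumption the genomic spacing of
    a kleisin pool is also the maximal size of its fully extruded loops.
    """
    genome = genome or GenomeModel()
    pools = dict(census.totals)
    pools[COMBINED_KLEISIN] = census.combined_kleisin_total

    total_bp = genome.total_dna_bp
    axis_um = census.total_axis_length_um
    rows = {}
    for name, n in pools.items():
        if n <= 0:
            raise ValueError(f"zero total for {name}")
        rows[name] = {
            "total": n,
            "per_chromatid": n / genome.n_chromatids,
            "per_um": n / axis_um,
            "per_Mb": n / (total_bp / 1e6),
            "genomic_spacing_kb": total_bp / n / 1e3,
            "physical_spacing_nm": axis_um * 1e3 / n,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subunit"
    table.attrs["phase"] = census.phase
    table.attrs["chromatid_genomic_length_Mb"] = genome.chromatid_genomic_length_bp / 1e6
    table.attrs["chromatid_physical_length_um"] = axis_um / genome.n_chromatids
    table.attrs["Mb_per_um"] = (total_bp / 1e6) / axis_um
    table.attrs["nm_per_Mb"] = axis_um * 1e3 / (total_bp / 1e6)
    # hierarchical loop sizes: large Condensin II loops subdivided by the
    # combined kleisin pool into subloops
    table.attrs["loop_size_CII_kb"] = table.loc["CAP-H2", "genomic_spacing_kb"]
    table.attrs["loop_size_combined_kb"] = table.loc[COMBINED_KLEISIN, "genomic_spacing_kb"]
    table.attrs["ratio_I_to_II"] = isoform_ratio(census)
    table.attrs["predicted_axial_spacing_CII_nm"] = table.loc["CAP-H2", "physical_spacing_nm"]
    return table


def holocomplex_count(kleisin_total: float, heat_total: float) -> tuple[float, float]:
    """Kleisin-limited holocomplex count and its fraction of the HEAT pool.

    The kleisin closes the pentameric ring, so the number of complete
    holocomplexes is bounded by min(kleisin, HEAT); the fraction says
    how many HEAT-repeat subunits can find a kleisin partner.
    """
    if kleisin_total < 0 or heat_total < 0:
        raise ValueError("totals must be >= 0")
    if heat_total == 0:
        raise ZeroDivisionError("fraction undefined for heat_total = 0")
    return min(kleisin_total, heat_total), kleisin_total / heat_total


def isoform_ratio(census: CondensinCensus) -> float:
    """Condensin I : Condensin II abundance ratio (CAP-H / CAP-H2)."""
    if census.totals["CAP-H2"] <= 0:
        raise ZeroDivisionError("CAP-H2 total must be > 0")
    return census.totals["CAP-H"] / census.totals["CAP-H2"]


def predicted_detection(
    census: CondensinCensus, efficiency: float, subunit: str = "CAP-H2"
) -> float:
    """Expected detected localizations per µm of chromatid axis.

    ``efficiency`` is the combined labeling-and-detection efficiency of
    the imaging chain (0 < efficiency <= 1).
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    return efficiency * census.totals[subunit] / census.total_axis_length_um


def round_like_report(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting precision: integers for counts, one decimal for kb/nm."""
    out = table.copy()
    for col in ("total", "per_chromatid", "per_um", "per_Mb"):
        out[col] = out[col].round().astype(int)
    for col in ("genomic_spacing_kb", "physical_spacing_nm"):
        out[col] = out[col].round(1)
    return out
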