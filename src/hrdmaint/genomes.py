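"""Reference genome geometry for scar scoring.

Only autosome lengths and centromere intervals are needed: telomeric allelic
imbalance requires telomere contact without centromere crossing, large-scale
state transitions are counted per chromosome arm, and whole-genome-duplication
fractions are length-weighted over autosomes.  Real-build tables (GRCh37 and
GRCh38 autosome lengths with cytoband-acen centromere intervals, approximate
by nature) are shipped alongside a configurable simplified build used by the
synthetic generator and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomeBuild", "get_build", "simplified_build", "GRCH37", "GRCH38"]


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths, centromere intervals and the autosome set."""

    name: str
    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]]  # (start, end), 1-based inclusive
    autosomes: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.autosomes is None:
            object.__setattr__(self, "autosomes", frozenset(self.chrom_lengths))
        for chrom, (cs, ce) in self.centromeres.items():
            if not 1 <= cs <= ce <= self.chrom_lengths[chrom]:
                raise ValueError(f"centromere outside chromosome bounds on {chrom}")

    def arm_of(self, chrom: str, start: int, end: int) -> str:
        """'p' / 'q' for a segment confined to one arm, 'span' otherwise."""
        cs, ce = self.centromeres[chrom]
        if end < cs:
            return "p"
        if start > ce:
            return "q"
        return "span"


_GRCH37_LEN = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}
_GRCH37_CEN = {
    "1": (121535434, 124535434), "2": (92326171, 95326171),
    "3": (90504854, 93504854), "4": (49660117, 52660117),
    "5": (46405641, 49405641), "6": (58830166, 61830166),
    "7": (58054331, 61054331), "8": (43838887, 46838887),
    "9": (47367679, 50367679), "10": (39254935, 42254935),
    "11": (51644205, 54644205), "12": (34856694, 37856694),
    "13": (16000000, 19000000), "14": (16000000, 19000000),
    "15": (17000000, 20000000), "16": (35335801, 38335801),
    "17": (22263006, 25263006), "18": (15460898, 18460898),
    "19": (24681782, 27681782), "20": (26369569, 29369569),
    "21": (11288129, 14288129), "22": (13000000, 16000000),
}
_GRCH38_LEN = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468,
}
_GRCH38_CEN = {
    "1": (122026459, 124932724), "2": (92188145, 94090557),
    "3": (90772458, 93655574), "4": (49712061, 51743951),
    "5": (46485900, 50059807), "6": (58553888, 59829934),
    "7": (58169653, 61528020), "8": (44033744, 45877265),
    "9": (43389635, 45518558), "10": (39686682, 41593521),
    "11": (51078348, 54425074), "12": (34769407, 37185252),
    "13": (16000000, 18051248), "14": (16000000, 18173523),
    "15": (17083673, 19725254), "16": (36311158, 38265669),
    "17": (22813679, 26616164), "18": (15460899, 20861206),
    "19": (24498980, 27190874), "20": (26436232, 30038348),
    "21": (10864560, 12915808), "22": (12954788, 15054318),
}

GRCH37 = GenomeBuild("grch37", _GRCH37_LEN, _GRCH37_CEN)
GRCH38 = GenomeBuild("grch38", _GRCH38_LEN, _GRCH38_CEN)


def get_build(name: str) -> GenomeBuild:
    builds = {"grch37": GRCH37, "grch38": GRCH38}
    try:
        return builds[name.lower()]
    except KeyError:
        raise ValueError(f"unknown genome build {name!r}; choose from {sorted(builds)}")


def simplified_build(
    n_chrom: int = 8,
    chrom_length: int = 200_000_000,
    centromere: tuple[int, int] = (95_000_000, 105_000_000),
) -> GenomeBuild:
    """A uniform toy genome of metacentric chromosomes for simulation and
    fast tests."""
    chroms = [str(i + 1) for i in range(n_chrom)]
    return GenomeBuild(
        name=f"simplified{n_chrom}",
        chrom_lengths={c: chrom_length for c in chroms},
        centromeres={c: centromere for c in chroms},
    )
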