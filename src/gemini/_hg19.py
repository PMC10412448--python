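"""Built-in hg19 autosome constants.

Chromosome lengths and centromere (acen) boundaries for the 22 human
autosomes of the hg19/GRCh37 assembly, embedded so that binning and
chromosome-arm bookkeeping never require a genome download.
"""

# Autosome lengths in bp, in karyotype order.
HG19_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
}

# Centromere (acen band) start/end per autosome, from the UCSC hg19
# cytoBand table.  p arm = [0, cen_start), q arm = [cen_end, length).
HG19_CENTROMERES: dict[str, tuple[int, int]] = {
    "chr1": (121535434, 124535434),
    "chr2": (92326171, 95326171),
    "chr3": (90504854, 93504854),
    "chr4": (49660117, 52660117),
    "chr5": (46405641, 49405641),
    "chr6": (58830166, 61830166),
    "chr7": (58054331, 61054331),
    "chr8": (43838887, 46838887),
    "chr9": (47367679, 50367679),
    "chr10": (39254935, 42254935),
    "chr11": (51644205, 54644205),
    "chr12": (34856694, 37856694),
    "chr13": (16000000, 19000000),
    "chr14": (16000000, 19000000),
    "chr15": (17000000, 20000000),
    "chr16": (35335801, 38335801),
    "chr17": (22263006, 25263006),
    "chr18": (15460898, 18460898),
    "chr19": (24681782, 27681782),
    "chr20": (26369569, 29369569),
    "chr21": (11288129, 14288129),
    "chr22": (13000000, 16000000),
}

# Acrocentric short arms carry no usable sequence in hg19 and are dropped
# from arm-level summaries, leaving 39 autosome arms.
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})


def autosome_arms() -> list[tuple[str, str, int, int]]:
    """The 39 autosome arms as (arm_name, chrom, start, end) half-open."""
    arms = []
    for chrom, length in HG19_AUTOSOME_LENGTHS.items():
        cen_start, cen_end = HG19_CENTROMERES[chrom]
        num = chrom.removeprefix("chr")
        if f"{num}p" not in ACROCENTRIC_P_ARMS:
            arms.append((f"{num}p", chrom, 0, cen_start))
        arms.append((f"{num}q", chrom, cen_end, length))
    return arms
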