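"""Bundled benchmark tables.

Two small published data sets ride along as worked-example fixtures:

* A ten-strain bacterial mock community, shotgun-sequenced on HiSeq, with the
  per-strain BLAST hit counts of the full run (~1.22 million reads, 101 b
  reads). The hit ratio n_i / s — each strain's hit count over the sum of all
  strains' hits — is the relative-abundance proxy the whole package estimates
  from small samples.
* Ten large public MG-RAST projects with, for each, the most-annotated phylum
  and class of the original full run versus a 5000-read sample taken from the
  start of the file, and the base counts of original and sample.

Everything here is a plain printed table; nothing is recomputed at import.
"""

from __future__ import annotations

READ_LENGTH = 101

# Per-strain BLAST hit counts against each strain's own reference genome,
# full mock-community run. Order: most to least abundant.
MOCK_COMMUNITY_HITS: dict[str, int] = {
    "Escherichia coli KCTC 2571": 30_658_032,
    "Escherichia coli Strain W": 29_390_176,
    "Staphylococcus epidermidis ATCC": 18_862_322,
    "Pseudomonas stutzeri ATCC 17588": 18_559_245,
    "Klebsiella pneumoniae KCTC 2242": 15_708_328,
    "Chromobacterium violaceum ATCC 12472": 15_466_319,
    "Polaromonas naphthalenivorans CJ2": 14_081_217,
    "Corynebacterium glutamicum ATCC 13032": 10_351_377,
    "Roseobacter denitrificans OCh114": 9_332_359,
    "Arthrobacter chlorophenolicus A6": 2_253_237,
}

MOCK_COMMUNITY_TOTAL_HITS = 164_662_612
assert sum(MOCK_COMMUNITY_HITS.values()) == MOCK_COMMUNITY_TOTAL_HITS

# Genomic GC fraction of each strain (published genome characteristics).
# The hit-ratio-weighted mean is ~0.539, so a simulated pool lands near the
# benchmark run's overall GC of ~53%.
MOCK_COMMUNITY_GC: dict[str, float] = {
    "Escherichia coli KCTC 2571": 0.506,
    "Escherichia coli Strain W": 0.509,
    "Staphylococcus epidermidis ATCC": 0.321,
    "Pseudomonas stutzeri ATCC 17588": 0.639,
    "Klebsiella pneumoniae KCTC 2242": 0.575,
    "Chromobacterium violaceum ATCC 12472": 0.648,
    "Polaromonas naphthalenivorans CJ2": 0.623,
    "Corynebacterium glutamicum ATCC 13032": 0.538,
    "Roseobacter denitrificans OCh114": 0.589,
    "Arthrobacter chlorophenolicus A6": 0.659,
}

# Most-annotated phylum and class, original full run vs 5000-read sample,
# for the ten public MG-RAST projects:
# (original id, sample id, rank, top taxon of original, top taxon of sample).
TOP_TAXON_PAIRS: list[tuple[str, str, str, str, str]] = [
    ("4539528.3", "4701886.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4510219.3", "4701884.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4510173.3", "4701887.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4509400.3", "4701883.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4562385.3", "4701888.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4538997.3", "4701892.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4539575.3", "4701885.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4587432.3", "4701891.3", "phylum", "Firmicutes", "Actinobacteria"),
    ("4555915.3", "4701890.3", "phylum", "Ascomycota", "Ascomycota"),
    ("4533611.3", "4701889.3", "phylum", "Proteobacteria", "Proteobacteria"),
    ("4539528.3", "4701886.3", "class", "Actinobacteria (class)", "Actinobacteria (class)"),
    ("4510219.3", "4701884.3", "class", "Deltaproteobacteria", "Deltaproteobacteria"),
    ("4510173.3", "4701887.3", "class", "Gammaproteobacteria", "Gammaproteobacteria"),
    ("4509400.3", "4701883.3", "class", "Actinobacteria (class)", "Actinobacteria (class)"),
    ("4562385.3", "4701888.3", "class", "Gammaproteobacteria", "Gammaproteobacteria"),
    ("4538997.3", "4701892.3", "class", "Alphaproteobacteria", "Deltaproteobacteria"),
    ("4539575.3", "4701885.3", "class", "Alphaproteobacteria", "Alphaproteobacteria"),
    ("4587432.3", "4701891.3", "class", "Actinobacteria (class)", "Actinobacteria (class)"),
    ("4555915.3", "4701890.3", "class", "Gammaproteobacteria", "Gammaproteobacteria"),
    ("4533611.3", "4701889.3", "class", "Alphaproteobacteria", "Alphaproteobacteria"),
]

# Base counts, original full run vs its 5000-read sample:
# (original id, original bases, sample id, sample bases).
PROJECT_BASE_PAIRS: list[tuple[str, int, str, int]] = [
    ("4539528.3", 37_968_936_507, "4701886.3", 306_684),
    ("4510219.3", 56_396_775_865, "4701884.3", 1_011_153),
    ("4510173.3", 37_220_314_566, "4701887.3", 505_000),
    ("4509400.3", 28_875_056_044, "4701883.3", 505_000),
    ("4562385.3", 30_079_534_981, "4701888.3", 749_082),
    ("4538997.3", 36_830_201_101, "4701892.3", 1_179_840),
    ("4539575.3", 19_954_890_565, "4701885.3", 434_006),
    ("4587432.3", 24_845_881_691, "4701891.3", 671_320),
    ("4555915.3", 17_546_603_952, "4701890.3", 505_000),
    ("4533611.3", 17_299_825_549, "4701889.3", 813_458),
]
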