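"""Published comparative-genomics reference values for *Comamonas
testosteroni* (14-strain study), used as inputs for ratio arithmetic and
power-law self-consistency checks.

These are observed quantities from the literature, not outputs of this
package: reproducing them from scratch would require the deposited genome
accessions plus external annotation services.
"""

ORF_COUNTS = {
    "JC8": 4935,
    "JC9": 4957,
    "JC12": 4948,
    "JC13": 4914,
    "JL14": 5416,
    "JL40": 5546,
    "D4": 4674,
    "DS1": 5400,
    "DF1": 5280,
    "DF2": 5294,
    "S44": 5147,
    "CNB-2": 5011,
    "ATCC 11996": 4998,
    "KF-1": 5645,
}

CORE_FAMILIES = 3599
PAN_FAMILIES = 10165
SINGLE_COPY_CORE = 3483

HEAPS_KAPPA = 1256.0
HEAPS_ALPHA = 0.639

GC_RANGE = (61.1, 61.8)  # percent
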