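"""Published reference data used for documented cross-checks.

The amplification primers below are the published validation primers of the
*B. pumilus* SAFR-032 genome update (junctions of the restored rRNA-operon
fragment, RRNAO_*, and of the transposase-flanked inversion, TRANS_*).  They
were selected with Primer3 for a 54–56 °C window under that program's own
thermodynamic defaults; under this package's declared Tm model they serve as
a tolerance check (±2 °C around the window), not as a design target.
"""

SAFR032_AMPLIFICATION_PRIMERS = {
    "RRNAO_AC01_fwd": "AATTCTTATCTCTTCTTTACAACAAG",
    "RRNAO_AC01_rev": "AAGATCATATTCCATTGCTTTATAAC",
    "RRNAO_AC04_fwd": "AATGAGAAAGTACTTGAAATCATTAG",
    "RRNAO_AC04_rev": "TTAAGAAGAATGGATTTGTAATAACG",
    "RRNAO_BD02_fwd": "GAATCATTAGAATTATGAAGGAAGAG",
    "RRNAO_BD02_rev": "AGCAATTGATACAAGATAATACTTTG",
    "RRNAO_BD09_fwd": "TCATTAGAATTATGAAGGAAGAGAAG",
    "RRNAO_BD09_rev": "TTAAATACGTAATACTTTCACCAATC",
    "RRNAO_CB00_fwd": "CTGTACTATTGTTGTTTATGTCAGG",
    "RRNAO_CB00_rev": "CTTCTATATCTCTTCCTAACACTTG",
    "RRNAO_CB07_fwd": "TTACATGTATCTATTAACCCTGTAAC",
    "RRNAO_CB07_rev": "TGATATATACATAATCACTACGAGAC",
    "TRANS_L05_fwd": "ATATTTATGGTGATACAATACAAGAG",
    "TRANS_L05_rev": "TCTTCAATACAGTTCAACATATAATG",
    "TRANS_L09_fwd": "GTTCGACTACTTAACGATTAATAAC",
    "TRANS_L10_rev": "AAATAATCAAGAAACCTATATCGAAG",
    "TRANS_R01_fwd": "GAAATATTTATTCTCGCATTATGAAC",
    "TRANS_R01_rev": "CCTATTACATGCTTTCGTTCTTC",
    "TRANS_R03_fwd": "AAATATTTATTCTCGCATTATGAACC",
    "TRANS_R05_rev": "CTATTACATGCTTTCGTTCTTC",
}

SAFR032_SEQUENCING_PRIMERS = {
    "16s_bpum_seq": "GCTGGAATCGCTAGTAATCGCGGATCAGCATG",
    "23s_bpum_seq1": "CACTAGGGAGTATTTAGCCTTGGGAGATGGTC",
    "23s_bpum_seq2": "CGCAAGGAAGTAAGATCCCTGAAAGATGATC",
}
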