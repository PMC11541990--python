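# Default region lists for mCA taxonomy (hg38-approximate coordinates).
#
# The canonical entries encode the CLL clinical FISH panel loci: del 6q,
# del 11q, trisomy 12, del 13q, del 17p, and CNN-LOH at 13q spanning the
# MIR16-1 locus.  The driver-candidate and lymphoid lists shipped here are
# small ILLUSTRATIVE examples for testing the interval rules; for faithful
# replication of published analyses supply the full published lists.
#
# All intervals are 0-based half-open.  Centromere positions are single
# approximate coordinates (the p arm is [0, centromere), the q arm is
# [centromere, length)).

genome_build: hg38-approx

arm_table:
  "1":  {centromere: 123400000, length: 248956422}
  "2":  {centromere: 93900000, length: 242193529}
  "3":  {centromere: 90900000, length: 198295559}
  "4":  {centromere: 50000000, length: 190214555}
  "5":  {centromere: 48800000, length: 181538259}
  "6":  {centromere: 59800000, length: 170805979}
  "7":  {centromere: 60100000, length: 159345973}
  "8":  {centromere: 45200000, length: 145138636}
  "9":  {centromere: 43000000, length: 138394717}
  "10": {centromere: 39800000, length: 133797422}
  "11": {centromere: 53400000, length: 135086622}
  "12": {centromere: 35500000, length: 133275309}
  "13": {centromere: 17700000, length: 114364328}
  "14": {centromere: 17200000, length: 107043718}
  "15": {centromere: 19000000, length: 101991189}
  "16": {centromere: 36800000, length: 90338345}
  "17": {centromere: 25100000, length: 83257441}
  "18": {centromere: 18500000, length: 80373285}
  "19": {centromere: 26200000, length: 58617616}
  "20": {centromere: 28100000, length: 64444167}
  "21": {centromere: 12000000, length: 46709983}
  "22": {centromere: 15000000, length: 50818468}
  "X":  {centromere: 60600000, length: 156040895}
  "Y":  {centromere: 10400000, length: 57227415}

canonical:
  - {chrom: "6", arm: q, type: loss}
  - {chrom: "11", arm: q, type: loss}
  - {chrom: "12", arm: whole, type: gain, min_fraction: 0.8}
  - {chrom: "13", arm: q, type: loss}
  - {chrom: "17", arm: p, type: loss}
  # CNN-LOH on 13q counts only when the call contains the MIR16-1 anchor
  # locus (13q14.2; approximate hg38 coordinates).
  - {chrom: "13", arm: q, type: cnn_loh, anchor: [50048100, 50049300]}

driver_candidates:
  # Example focal CLL-driver regions (a call is a driver when it fully
  # contains a candidate of matching type).
  - {chrom: "2", start: 60000000, end: 62000000, type: gain}    # 2p16 / BCL11A-REL region
  - {chrom: "8", start: 200000, end: 10000000, type: loss}      # 8p telomeric loss
  - {chrom: "8", start: 127000000, end: 128000000, type: gain}  # 8q24 / MYC region
  - {chrom: "10", start: 102000000, end: 104000000, type: loss} # 10q24 region
  - {chrom: "14", start: 105000000, end: 106500000, type: loss} # 14q32 / IGH-proximal region

lymphoid:
  # Example lymphoid-malignancy-associated entries; deliberately overlaps
  # the canonical panel (categories are not a partition) and contains no
  # sex-chromosome entries.
  - {chrom: "11", arm: q, type: loss}
  - {chrom: "12", arm: whole, type: gain, min_fraction: 0.8}
  - {chrom: "13", arm: q, type: loss}
  - {chrom: "10", arm: q, type: loss}
  - {chrom: "14", arm: q, type: cnn_loh}
  - {chrom: "22", arm: q, type: loss}
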