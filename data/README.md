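# External data (not bundled)

`scripts/acceptance.py` and the optional accession-benchmark tests expect
the BMRB entry 15716 NMR-STAR deposition here as `bmr15716.str`. The
library performs no network access; download it yourself, e.g.:

    curl -L -o data/bmr15716.str \
        https://bmrb.io/ftp/pub/bmrb/entry_directories/bmr15716/bmr15716_3.str

Without the file, the acceptance report is written empty and the benchmark
tests skip.
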