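# ssassign

Automated backbone and side-chain chemical-shift assignment for solid-state
NMR (ssNMR) peak lists, with a synthetic peak-list generator and a
completeness/correctness evaluator.

Given a protein sequence and picked peak lists from carbon/nitrogen-detected
MAS ssNMR experiments (NCA, NCO, NCACX, NCOCX, CANCOCX, CC, ...), the
assigner:

1. builds **spin systems** anchored on CO(i−1)/N(i)/CA(i) root triples —
   found directly in CA-N-CO-correlating experiments or by joining N/CO and
   N/CA experiments on the shared nitrogen — and attaches strip peaks from
   every experiment within a spectral tolerance;
2. repeats the assembly over a grid of tolerances and keeps the one with the
   best data-quality score (spin-system and sequential-link yields against
   the counts the sequence predicts); a quality gate stops early with a
   "more information is required" message when the data cannot support an
   assignment;
3. links spin systems into di-peptide chains, scores pentapeptide fragments
   against sequence windows, and runs **loopy belief propagation** over a
   factor graph of candidate placements (amino-acid typing likelihoods from
   bundled BMRB-derived Gaussian shift statistics, link factors rewarding
   sequential placement, soft one-to-one exclusion) to obtain per-residue
   marginal assignment probabilities;
4. estimates per-experiment **referencing offsets** (median residual between
   peaks predicted from confident assignments and observed peaks — a
   simplified surrogate for LACS, see *Divergences*), applies them, and
   iterates to convergence;
5. assigns **side-chain carbons** by optimal matching of leftover strip
   carbons against the residue type's atom inventory.

Results are written as NMR-STAR 2.1/3.1 shift tables, a Sparky resonance
list, a per-residue probability report (green/cyan/yellow/red/gray bins) and
a referencing-offset report.

## Command line

```sh
# registry of the 14 supported experiments (* = minimum required set)
ssassign profiles

# simulate sequential-cross-peak lists from an assigned shift table
ssassign simulate shifts.txt -e CC,NCA,NCO,NCACX,NCOCX,CANCOCX \
    --seed 7 --jitter-c 0.1 --missing-rate 0.1 --out peaks/

# assign: sequence + EXPERIMENT=peaklist pairs
ssassign assign seq.txt NCA=peaks/NCA.list NCO=peaks/NCO.list \
    CC=peaks/CC.list NCACX=peaks/NCACX.list NCOCX=peaks/NCOCX.list \
    CANCOCX=peaks/CANCOCX.list --out out/

# score an assignment against a reference table (default cutoff 0.6)
ssassign evaluate out/shifts_nmrstar31.str reference.str
```

Peak lists are read from Sparky `.list`, XEASY `.peaks`, or tab-separated
`.txt` (position columns in the experiment's axis order, then an optional
height; `--format`/`format_hint` overrides extension-based detection).
Sequences are plain ASCII in one- or three-letter codes. Shift tables are
NMR-STAR 2.1/3.1 or simple 4-column text (`index residue atom ppm`).

## Divergences from the full pipeline this reimplements

* Referencing errors are estimated by a robust median-residual comparison of
  predicted vs. observed peaks per experiment, not by the full LACS
  regression.
* Side chains are assigned by Gaussian-likelihood optimal matching with a
  posterior over statistically distinct alternatives, not by the complete
  Bayesian network of the parent solution-NMR engine; statistically
  overlapping atoms (e.g. Phe ring carbons) deliberately receive discounted
  probabilities, and stereo pairs (CD1/CD2 etc.) are ordered
  ascending-shift-to-ascending-name.
* Typing statistics are a bundled static snapshot of public BMRB averages
  (`src/ssassign/data/shift_stats.tsv`, user-overridable) and are not
  conditioned on secondary structure.
* Secondary-structure prediction output and the web-submission machinery of
  the original server are out of scope.
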