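# ecgkit

Automated discrimination of arrhythmias in single-lead ECG, built as a
four-stage cascade with no prior assumption about which arrhythmia (if any)
is present — the situation a wearable or Holter analysis pipeline faces.
It is a library plus a small CLI, aimed at physiological-signal researchers
and engineers who need a transparent, testable baseline arrhythmia
classifier and a labelled synthetic-ECG generator to exercise it.

## The method

Every recording is resampled to 300 Hz, band-pass filtered (3rd-order
Butterworth, 0.4–30 Hz, zero-phase), cut into 8 s windows (2400 samples,
3 s overlap by default) and standardised to zero mean, unit variance.
Each window then passes through a strict decision chain:

1. **VF vs non-VF.** Six features: four from binary images of the lag-1 and
   lag-5 phase plots (self-similarity `F1 = P₂/S − P₁/S`; the count `F2`
   and covered pixels `F3` of 45°-slanted line structures longer than 20
   px; the filled-pixel fraction `F4` of the morphologically hole-filled
   difference image B1 − B2), the count `F5` of spectral bins above the
   mean single-sided amplitude (0.125 Hz resolution), and the normalized
   Shannon entropy `F6 = −Σ pᵢ log₂ pᵢ / log₂ n` of the amplitude
   histogram. Disorganized VF fills the phase plane, concentrates spectral
   energy, and raises entropy.
2. **AF vs non-AF.** R peaks from a Pan–Tompkins-style detector; after
   excluding non-physiologic and ectopic intervals, three RR statistics:
   normalized Shannon entropy, turning point ratio (fraction of interior
   strict local extrema; ≈ 2/3 for an iid sequence) and RMSSD / mean RR.
   "Irregularly irregular" AF pushes all three up.
3. **PVC vs N beats.** 200-sample beat windows (R at index 70); features:
   peak-to-valley amplitude (LMMD), maximum spectral amplitude (MSA),
   normalized wavelet-coefficient Shannon entropy (db4, 4 levels), and
   population kurtosis `E[(X−μ)⁴]/E[(X−μ)²]²`.
4. **Pattern grammar.** Per-beat 0/1 PVC labels → episode code 1–7 via the
   longest PVC run (0 → NSR, 2 → couplet, 3 → triplet, ≥4 → VT) and, for
   isolated PVCs, the modal spacing of their positions (2/3/4 → bigeminy /
   trigeminy / quadrigeminy). Codes over all windows form the vector of
   episode type (VET).

Stages 1–3 use either a binary decision tree or a linear SVM (C = 1),
evaluated with both a 5-trial unbalanced half/half protocol and a 5×5
balanced subsampling protocol (25 trials). A seeded synthetic generator
(PQRST Gaussian-bump templates; widened, larger, P-free PVC beats; iid
0.4–1.2 s RR for AF; drifting oscillator mixtures for VF) provides exact
ground truth for all of it.

## Worked example

```sh
ecgkit synth --rhythm bg --duration 32 --seed 7 --out rec.csv --truth truth.csv
ecgkit preprocess --in rec.csv --format csv --step 5 --out segs.npz
ecgkit vf-features --in segs.npz --out vf.csv
ecgkit classify --in rec.csv --seed 4 --step 8 --out vet.csv
```

The first command writes 32 s of synthetic bigeminy ("wrote 9600 samples
(32.0 s) of bg to rec.csv"). Preprocessing yields 5 overlapped windows;
`vf.csv` starts

```
start_s,F1,F2,F3,F4,F5,F6
0.0,0.011740625000000001,151.0,6965.0,0.0376484375,178.0,0.6191796681527058
```

— an organized rhythm: low self-similarity difference F1, high
above-mean-bin count F5, low amplitude entropy F6. `classify` (here
trained on synthetic data, seed 4) prints "classified 4 segments ->
vet.csv" and every 8 s window is labelled bigeminy:

```
segment_index,start_s,stage1,stage2,episode_code,episode_name
0,0.0,non-VF,non-AF,5,bigeminy
1,8.0,non-VF,non-AF,5,bigeminy
...
```

`ecgkit train` fits and evaluates a single stage from feature/label CSVs
and saves a portable JSON model usable with `ecgkit classify --models`.
WFDB records (`.hea`/`.dat`, formats 16 and 212) are read with
`--format wfdb`.

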