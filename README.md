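# paleoherd

Biomolecular zooarchaeology of herd management: a Python toolkit for the
analysis chain applied to faunal assemblages from pastoral sites —
collagen peptide-mass-fingerprint taxonomy (ZooMS), cosine modelling of
sequentially sampled tooth-enamel δ18O for birth-season estimation,
threshold-based C3/C4 diet reconstruction from enamel and collagen δ13C,
and assemblage-level count statistics. A synthetic-data module generates
inputs with known ground truth, so the whole chain is testable without
access to excavated material.

## Who it is for

Zooarchaeologists and isotope analysts who have (a) MALDI-ToF peak lists
from collagen fingerprinting, (b) intra-tooth δ18O/δ13C sequences from
sheep/goat molars, (c) bulk enamel and bone-collagen isotope tables, and
(d) NISP or seed count tables, and who want the standard decision rules
of the field applied reproducibly rather than in a spreadsheet.

## The models

**ZooMS.** Each taxon's collagen yields tryptic peptides with diagnostic
masses; observed peaks are matched within ±0.2 Da (configurable). The
COL1α2 757 oxidation pair separates sheep (m/z 3017.4/3033.4) from goat
(3077.4/3093.4); COL1α2 375 (1154, 2028, 2044) flags Caprines;
Antilopini-specific masses (1182, 2056, 2072, 1532), a gazelle marker
(3227) and a red-deer marker (2216) discriminate gazelle from deer, with
insufficient evidence degrading to the composite *Gazella/Cervus*.

**Seasonality.** Enamel mineralises sequentially, so δ18O drilled along
the crown records the annual cycle. The modelled value at distance *x*
(mm) from the enamel–root junction is

    δ18O_m(x) = A·cos(2π·(x − x0)/X) + M

with half-amplitude *A*, period *X* (crown length per annual cycle),
delay *x0* (position of the δ18O maximum) and mean *M*. Fits are
accepted when the Pearson correlation between observed and modelled
values satisfies r ≥ 0.92, X ≥ 16.0 mm, and the sequence shows a genuine
sinusoid with a clear maximum. The normalised phase x0/X ∈ [0, 1) is a
proxy for season of birth, compared against reference ranges from modern
herds; upper sheep M3 ratios are corrected by +0.073 of a cycle.

**Diet.** Consumer δ13C = plant δ13C + tissue enrichment (e\* ≈ +14.1‰
for ruminant enamel; +5‰ for collagen). From a modern global C3 mean of
−26.0‰ (Suess-corrected +1.5‰) and a local archaeological C3 maximum of
−22.8‰, threshold values in enamel separate canopy feeding, open pure-C3
diets and C4 contributions; collagen expectations are −19.5‰ (average-
based) and −17.8‰ (maximum-based). Collagen is quality-controlled by the
atomic C:N ratio (accept 3.2–3.62).

**Statistics.** %NISP share tables, chi-square uniformity of counts
across stratigraphic horizons, the Shapiro–Wilk → Levene →
ANOVA/Kruskal–Wallis group-comparison flow, and Spearman rank
correlation, all at α = 0.05.

## Worked example

```python
import paleoherd as ph

# a simulated sheep M3 born at phase 0.35 of the annual cycle
params = ph.SequenceSimParams(birth_phase=0.35, noise_sd=0.3, seed=42)
seq, truth = ph.simulate_tooth_sequence(params, specimen_id="DEMO")
fit = ph.accept_fit(ph.fit_cosine(seq))
est = ph.normalized_birth_position(fit, "sheep", "M3", "upper")

spec = ph.simulate_spectrum("Capra", jitter_sd=0.05, decoy_peaks=6, seed=7)
assignment = ph.classify_spectrum(spec)
```

This prints (via the fields of the returned objects):

```
A=2.49 x0=10.30 X=30.88 M=-5.66 r=0.990 accepted=True
x0/X = 0.406 (corrected=True); truth = 0.35
Capra genus 5
```

The fitter recovers the simulated amplitude (2.5‰), period (30 mm) and
mean (−5.5‰) from 10 noisy samples; r = 0.990 clears the 0.92 acceptance
threshold. The birth-position ratio 0.406 includes the +0.073 upper-M3
correction (raw ratio 0.333 vs the simulated truth 0.35, i.e. recovery
to within 0.02 of a cycle). The goat spectrum is classified *Capra* at
genus rank on 5 matched markers.

Diet arithmetic from the measured plant baselines:

```python
ph.plant_baseline_from_samples([-24.0, -22.8])   # (-23.4, -22.8)
ph.collagen_c3_expectation()                     # (-19.5, -17.8)
cut = ph.derive_enamel_cutoffs(group="ruminant")
cut.derived    # (-10.4, -8.7, -14.1)
cut.published  # (-10.7, -9.0, -14.5)  <- classification default
ph.classify_enamel(-8.6, cut).label              # 'C4_contribution'
ph.classify_enamel(-12.0, cut).label             # 'pure_C3'
```

A thin CLI mirrors the stages: `paleoherd sim ...`, `paleoherd classify`,
`paleoherd seasons`, `paleoherd diet enamel|collagen`,
`paleoherd stats shares|chisq`.

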