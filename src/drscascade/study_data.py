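"""Published summary numbers of the in vivo colorectal DRS study.

The patient-level spectra of the study this pipeline models are not public;
what *is* published are per-class summary metrics and the per-location
confusion counts of the surgeon-comparison analysis.  Those printed tables
are frozen here as inputs, so the package's metric arithmetic can be
cross-checked against them (the counts are data, the metrics are always
recomputed by the code).
"""

from .evaluation import ConfusionCounts

#: Spectra acquired per tissue class (fat / healthy wall / tumor); tumor
#: drops to 87 after removing inconclusive-histopathology measurements.
REPORTED_SPECTRA_COUNTS = {"fat": 402, "wall": 282, "tumor": 151}
REPORTED_TUMOR_SPECTRA_AFTER_EXCLUSION = 87

#: Published per-class mean one-vs-all accuracies of the cascade.
REPORTED_ACCURACY = {"fat": 0.92, "wall": 0.89, "tumor": 0.94}
REPORTED_MCC = {"fat": 0.83, "wall": 0.77, "tumor": 0.73}

#: Counts used when weighting the average accuracy over tissue types
#: (tumor after exclusion of inconclusive measurements).
REPORTED_WEIGHTING_COUNTS = {"fat": 402, "wall": 282, "tumor": 87}

#: Surgeon-uncertain locations: 2x2 tables of each rater vs histopathology,
#: with healthy = fat + wall and tumor the positive class.
#: Surgeon: 16 healthy-truth called healthy, 36 called tumor; both tumor
#: locations called tumor.  Classifier (zero-false-negative threshold):
#: 39 healthy-truth called healthy, 13 called tumor; both tumors called tumor.
UNCERTAIN_SURGEON_COUNTS = ConfusionCounts(tp=2, tn=16, fp=36, fn=0)
UNCERTAIN_CLASSIFIER_COUNTS = ConfusionCounts(tp=2, tn=39, fp=13, fn=0)
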