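"""Shared vocabulary of the assay design.

The panel design: serum-starved cells are stimulated with a growth-factor
ligand at a low (1 ng/ml) or high (100 ng/ml) dose and lysed at 10, 30 or
90 minutes; phospho-ERK and phospho-AKT ELISA signals are recorded in
duplicate together with unstimulated time-0 controls.  All signal values are
carried in the log10 domain.
"""

import math

#: Closed set of downstream readouts; the analysis is defined only for these.
TARGETS = ("pERK", "pAKT")

#: Minutes after stimulation at which lysates are taken (0 = unstimulated control).
TIMES = (0, 10, 30, 90)

#: Post-stimulation time points (the kinetic-trajectory support).
POST_TIMES = (10, 30, 90)

#: Ligand doses in ng/ml.
DOSES = (1.0, 100.0)
LOW_DOSE, HIGH_DOSE = DOSES

#: Ligand label used for unstimulated time-0 control rows.
CONTROL_LIGAND = "control"

#: Breast cancer cell-line subtypes.
SUBTYPES = ("TNBC", "HER2amp", "HRpos")

#: Kinetic trajectory classes.
KINETIC_CLASSES = ("sustained", "transient", "late", "none")

#: Dose-sensitivity classes.
SENSITIVITY_CLASSES = ("equal", "high_greater", "high_only", "none")

#: Basal analyte measurement kinds.
KINDS = ("expression", "phosphorylation")

#: log10(1.2): the ~1.2-fold change equivalent of the 2-SD significance rule.
LOG10_1P2 = math.log10(1.2)
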