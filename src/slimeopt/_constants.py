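"""Classical constant tables for the fixed-dimension benchmark functions.

The canonical De Jong / Dixon-Szegő values: the foxholes grid, Kowalik
measurements, Hartmann coefficient matrices, and the Shekel wells.
"""

import numpy as np

# De Jong foxholes: a_ij is a 2 x 25 grid over {-32,-16,0,16,32}^2.
_g = np.array([-32.0, -16.0, 0.0, 16.0, 32.0])
FOXHOLES_A = np.vstack([np.tile(_g, 5), np.repeat(_g, 5)])  # (2, 25)

# Kowalik's problem: 11 measurements.
KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
     0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
KOWALIK_B = 1.0 / np.array(
    [0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0]
)

# Hartmann 3-D.
HARTMANN3_A = np.array(
    [[3.0, 10.0, 30.0],
     [0.1, 10.0, 35.0],
     [3.0, 10.0, 30.0],
     [0.1, 10.0, 35.0]]
)
HARTMANN3_C = np.array([1.0, 1.2, 3.0, 3.2])
HARTMANN3_P = np.array(
    [[0.3689, 0.1170, 0.2673],
     [0.4699, 0.4387, 0.7470],
     [0.1091, 0.8732, 0.5547],
     [0.0381, 0.5743, 0.8828]]
)

# Hartmann 6-D.
HARTMANN6_A = np.array(
    [[10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
     [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
     [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
     [17.0, 8.0, 0.05, 10.0, 0.1, 14.0]]
)
HARTMANN6_C = np.array([1.0, 1.2, 3.0, 3.2])
HARTMANN6_P = np.array(
    [[0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
     [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
     [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
     [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381]]
)

# Shekel wells (first m rows used for the 5/7/10-term variants).
SHEKEL_A = np.array(
    [[4.0, 4.0, 4.0, 4.0],
     [1.0, 1.0, 1.0, 1.0],
     [8.0, 8.0, 8.0, 8.0],
     [6.0, 6.0, 6.0, 6.0],
     [3.0, 7.0, 3.0, 7.0],
     [2.0, 9.0, 2.0, 9.0],
     [5.0, 5.0, 3.0, 3.0],
     [8.0, 1.0, 8.0, 1.0],
     [6.0, 2.0, 6.0, 2.0],
     [7.0, 3.6, 7.0, 3.6]]
)
SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])
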