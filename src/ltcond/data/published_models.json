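{
 "t2d_bmi_age": {
  "covariates": [
   {
    "name": "bmi",
    "coefficient": 0.08,
    "mean": 26.5
   },
   {
    "name": "age",
    "coefficient": 0.029,
    "mean": 50
   }
  ],
  "affine": -1.38
 },
 "t2d_bmi": {
  "covariates": [
   {
    "name": "bmi",
    "coefficient": 0.08,
    "mean": 26.5
   }
  ],
  "affine": -1.44
 },
 "t2d_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.029,
    "mean": 50
   }
  ],
  "affine": -1.28
 },
 "prostate_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.049,
    "mean": 50
   }
  ],
  "affine": -2.49
 },
 "lung_age_smoking": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.03,
    "mean": 50
   },
   {
    "name": "smoking",
    "coefficient": 2.6,
    "mean": 0.25
   }
  ],
  "affine": -3.06
 },
 "lung_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.04,
    "mean": 50
   }
  ],
  "affine": -3.3
 },
 "lung_smoking": {
  "covariates": [
   {
    "name": "smoking",
    "coefficient": 2.04,
    "mean": 0.25
   }
  ],
  "affine": -2.37
 },
 "breast_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.032,
    "mean": 50
   }
  ],
  "affine": -2.26
 },
 "ra_age_sex": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.022,
    "mean": 50
   },
   {
    "name": "sex",
    "coefficient": 0.32,
    "mean": 0.5
   }
  ],
  "affine": -2.46
 },
 "ra_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.022,
    "mean": 50
   }
  ],
  "affine": -2.46
 },
 "ra_sex": {
  "covariates": [
   {
    "name": "sex",
    "coefficient": 0.32,
    "mean": 0.5
   }
  ],
  "affine": -2.34
 },
 "eskd_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.02,
    "mean": 50
   }
  ],
  "affine": -2.08
 },
 "amd_age_bmi30": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.03,
    "mean": 50
   },
   {
    "name": "bmi30",
    "coefficient": 0.61,
    "mean": 0.3
   }
  ],
  "affine": -2.0
 },
 "amd_age": {
  "covariates": [
   {
    "name": "age",
    "coefficient": 0.04,
    "mean": 50
   }
  ],
  "affine": -2.1
 },
 "amd_bmi30": {
  "covariates": [
   {
    "name": "bmi30",
    "coefficient": 0.35,
    "mean": 0.3
   }
  ],
  "affine": -1.72
 }
}
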