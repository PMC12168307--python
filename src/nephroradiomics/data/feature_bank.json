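{
  "version": "1.0",
  "n_bins": 32,
  "image_types": [
    "original",
    "log-sigma-1-0-mm-3D",
    "log-sigma-2-0-mm-3D",
    "wavelet-LLL",
    "wavelet-LLH",
    "wavelet-LHL",
    "wavelet-LHH",
    "wavelet-HLL",
    "wavelet-HLH",
    "wavelet-HHL",
    "wavelet-HHH",
    "shotnoise",
    "binomialblur",
    "specklenoise",
    "gaussiannoise"
  ],
  "shape": [
    "VoxelVolume", "VoxelCount", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness1", "Compactness2", "SphericalDisproportion",
    "Maximum3DDiameter", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness", "Extent",
    "BoundingBoxVolume"
  ],
  "firstorder": [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity"
  ],
  "glcm": [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "InverseVariance", "JointEnergy", "JointEntropy", "MaximumProbability",
    "SumEntropy", "SumSquares"
  ],
  "glrlm": [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis"
  ],
  "glszm": [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis"
  ],
  "gldm": [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis"
  ],
  "ngtdm": ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
}
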