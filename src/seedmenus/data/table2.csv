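species,growth_form,perennial_forb,n,AUC,TSS,AHM,CMD,WP,SP,Tmax,Tmin,Trange,HLI,Slope,TPI,Text,AMP_MAXN,SWS
Echinocereus engelmannii,cactus,0,505,0.901,0.699,13.68,3.71,7.13,7.60,7.69,5.53,14.24,0.00,0.91,9.92,14.60,10.80,4.17
Opuntia basilaris,cactus,0,967,0.852,0.571,5.82,11.81,9.25,7.14,5.56,8.60,12.28,0.00,8.96,10.25,14.66,2.17,3.52
Acmispon humistratus,forb,0,196,0.888,0.678,6.95,7.04,2.22,2.08,12.99,13.60,11.50,0.48,6.55,9.00,0.46,27.14,0.00
Acmispon strigosus,forb,0,352,0.902,0.677,7.72,3.70,14.98,14.82,8.09,10.58,18.85,0.00,6.95,5.50,3.60,5.21,0.00
Amsinckia tessellata,forb,0,889,0.828,0.538,9.82,0.00,7.21,17.46,9.68,12.69,10.35,0.94,3.78,7.13,4.65,14.95,1.33
Asclepias erosa,forb,1,108,0.894,0.733,8.26,2.62,15.25,7.85,5.79,16.67,14.05,6.93,11.43,2.16,7.56,0.81,0.64
Astragalus didymocarpus,forb,0,152,0.884,0.694,9.48,0.96,6.79,22.75,17.84,12.29,7.65,3.93,0.75,5.29,8.86,2.69,0.71
Astragalus layneae,forb,1,168,0.922,0.76,18.14,3.20,4.96,16.89,22.43,1.07,3.54,0.64,3.89,9.66,6.78,4.35,4.45
Baileya multiradiata,forb,1,242,0.902,0.688,8.40,7.58,5.64,29.67,8.11,12.56,6.78,1.67,3.19,9.29,4.92,2.19,0.00
Chylismia brevipes,forb,0,806,0.858,0.611,14.38,4.99,10.89,21.51,6.00,7.00,5.18,0.48,6.27,4.91,13.35,3.09,1.94
Cryptantha micrantha,forb,0,513,0.857,0.594,8.87,3.39,16.92,10.92,8.45,12.80,13.95,0.55,3.23,6.97,6.17,7.79,0.00
Cryptantha nevadensis,forb,0,880,0.837,0.549,8.24,6.12,13.61,22.87,4.55,10.99,7.58,1.09,9.67,7.35,0.00,6.12,1.81
Descurainia pinnata,forb,0,740,0.86,0.602,5.91,4.92,13.29,8.08,6.53,11.00,16.63,0.19,7.62,6.49,5.28,14.08,0.00
Eriogonum inflatum,forb,1,1395,0.858,0.584,6.51,7.45,7.71,10.35,6.50,6.27,5.79,1.61,21.25,6.28,6.88,4.99,8.40
Euphorbia albomarginata,forb,1,484,0.886,0.659,8.83,4.09,14.55,8.76,9.70,14.06,19.35,4.15,2.98,3.94,3.67,3.27,2.65
Lepidium lasiocarpum,forb,0,1210,0.863,0.606,3.11,11.16,5.87,19.39,8.81,11.87,13.00,2.79,3.48,2.86,7.96,9.70,0.00
Lupinus odoratus,forb,0,45,0.97,0.919,9.97,5.68,13.09,22.51,14.41,0.00,0.00,0.00,7.93,9.52,16.88,0.00,0.00
Malacothrix glabrata,forb,0,744,0.837,0.554,14.33,3.47,14.26,13.97,5.72,7.97,11.64,1.73,2.87,10.59,3.88,5.89,3.67
Mirabilis laevis,forb,1,341,0.893,0.669,6.93,10.60,3.57,13.25,11.70,0.48,18.76,0.00,10.92,1.82,14.05,5.09,2.83
Oenothera cespitosa,forb,1,94,0.944,0.814,6.59,1.75,14.37,10.15,27.20,8.74,6.74,1.32,4.12,3.58,15.43,0.00,0.00
Oenothera deltoides,forb,0,299,0.916,0.759,11.81,12.21,5.02,11.51,5.35,18.49,3.07,12.84,7.71,4.91,1.39,4.89,0.80
Oenothera primiveris,forb,0,88,0.898,0.701,2.96,20.82,4.50,9.05,8.20,12.68,2.09,3.21,13.77,15.97,2.98,3.09,0.69
Penstemon palmeri,forb,1,203,0.922,0.775,5.84,3.46,7.77,30.51,10.27,5.51,0.00,1.59,6.39,9.91,16.49,2.27,0.00
Plantago ovata,forb,0,1208,0.862,0.588,10.68,6.81,6.34,7.59,22.63,10.58,4.39,2.06,5.70,9.93,6.70,2.36,4.23
Salvia columbariae,forb,0,687,0.864,0.596,7.31,3.59,5.38,14.98,11.18,10.62,12.13,1.67,10.80,3.73,7.94,8.55,2.12
Sphaeralcea ambigua,forb,1,1458,0.831,0.528,16.55,3.30,5.23,13.02,12.92,3.76,12.18,1.44,0.63,8.12,12.55,2.82,7.48
Stephanomeria exigua,forb,0,222,0.899,0.712,1.32,4.81,16.84,10.56,5.41,6.57,28.60,0.88,3.32,15.71,1.76,3.48,0.74
Achnatherum hymenoides,grass,0,530,0.836,0.57,8.76,4.19,5.13,4.38,10.80,16.22,17.96,4.05,5.65,11.21,6.32,3.99,1.34
Hilaria rigida,grass,0,658,0.871,0.611,5.22,11.10,7.86,14.76,7.19,11.47,15.20,1.77,6.22,2.57,4.93,9.89,1.82
Muhlenbergia porteri,grass,0,418,0.915,0.733,11.46,7.01,5.96,23.61,7.65,10.56,16.40,0.00,0.79,0.32,7.19,8.25,0.78
Vulpia octoflora,grass,0,532,0.868,0.605,3.35,8.94,9.35,9.21,9.90,5.30,12.15,4.54,16.65,13.49,1.43,0.00,5.68
Ambrosia dumosa,shrub,0,2524,0.822,0.496,21.45,6.53,7.71,15.43,5.98,4.60,8.27,2.61,7.62,9.30,4.44,6.07,0.00
Ambrosia salsola,shrub,0,1280,0.831,0.531,16.83,6.40,11.18,13.55,9.85,4.54,10.11,0.27,3.43,10.90,4.85,8.09,0.00
Atriplex hymenelytra,shrub,0,305,0.92,0.742,0.00,5.51,0.83,19.42,17.60,10.90,12.11,0.77,13.77,2.92,4.86,7.26,4.05
Encelia farinosa,shrub,0,892,0.896,0.659,0.00,14.74,3.56,9.66,5.97,9.23,6.93,2.49,11.54,6.00,22.34,4.87,2.66
Ephedra nevadensis,shrub,0,1972,0.84,0.557,15.78,5.72,9.41,9.26,13.06,7.21,13.40,1.16,7.51,6.10,3.83,5.54,2.02
Ericameria cooperi,shrub,0,433,0.921,0.727,10.48,0.00,7.19,14.46,24.13,7.02,10.56,1.45,4.79,4.76,3.59,8.96,2.62
Eriogonum fasciculatum,shrub,0,1098,0.872,0.6,14.07,4.52,9.87,9.59,10.14,3.36,10.40,4.62,8.85,3.28,10.31,9.33,1.66
Krameria bicolor,shrub,0,272,0.92,0.732,3.75,13.60,9.45,8.08,7.26,12.26,12.89,1.10,9.29,3.39,18.93,0.00,0.00
Krameria erecta,shrub,0,798,0.885,0.637,8.25,12.89,5.38,14.47,6.84,11.69,8.83,0.00,8.17,3.86,8.76,10.86,0.00
Larrea tridentata,shrub,0,2337,0.833,0.521,17.52,8.65,11.66,14.03,7.49,4.01,3.10,1.82,7.85,10.97,4.78,8.12,0.00
Lycium andersonii,shrub,0,653,0.861,0.583,4.76,6.20,11.35,17.20,11.12,9.70,19.77,1.41,0.84,1.49,4.12,6.28,5.77
Lycium cooperi,shrub,0,306,0.88,0.638,10.85,12.39,1.83,14.40,19.09,11.44,14.18,0.51,5.41,6.01,0.00,3.89,0.00
Lycium pallidum,shrub,0,131,0.902,0.698,1.30,24.08,11.61,14.27,1.06,14.66,10.34,1.37,4.01,2.23,7.16,0.00,7.91
Psorothamnus fremontii,shrub,0,444,0.894,0.672,9.24,4.83,10.46,16.23,12.72,11.90,9.40,0.75,12.51,6.26,3.39,0.00,2.31
Stephanomeria parryi,shrub,0,100,0.926,0.815,8.29,3.34,5.07,19.68,21.26,0.00,20.69,0.00,8.14,2.14,5.65,2.31,3.42
Chilopsis linearis,tree,0,330,0.9,0.688,0.00,20.18,19.65,4.70,5.16,4.60,4.47,1.72,0.72,8.84,19.62,6.20,4.13
Yucca brevifolia,tree,0,1633,0.875,0.622,10.11,3.70,5.09,10.52,8.11,12.64,15.24,0.16,6.97,9.27,4.10,4.61,9.49
Yucca schidigera,tree,0,1123,0.884,0.668,10.26,7.38,5.82,15.88,6.16,7.76,11.81,0.00,11.91,3.79,13.13,6.09,0.00
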