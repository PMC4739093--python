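# Reference table for the 29 countries where FGM/C is concentrated, transcribed
# from the most recent DHS/MICS country reports available at the 2013 reference
# date: prevalence among women 15-49 and girls 15-19, the customary age window
# for cutting, and the type-III (infibulation) share of each prevalence cohort.
# Percentages keep the printed decimal-comma style. Empty type-III cells mean
# the survey reports no typology breakdown for that country; the loader stores
# an assumed-zero share with an explicit flag.
country;prev_15_49;prev_15_19;cut_age_min;cut_age_max;type3_15_49;type3_15_19;source
Benin;7,3 %;2,0 %;0;14;12,5 %;8,7 %;DHS 2011-12
Burkina Faso;75,8 %;57,7 %;0;4;1,2 %;0,7 %;DHS 2010
Cameroon;1,4 %;0,4 %;5;9;5 %;5 %;DHS 2004
Central African Republic;24,2 %;17,9 %;5;14;7 %;9,5 %;MICS 2010
Chad;44,2 %;41,0 %;0;9;7,2 %;8,3 %;MICS 2010
Côte d'Ivoire;38,2 %;31,3 %;0;5;8,7 %;10,4 %;DHS 2012
Djibouti;93,1 %;89,5 %;5;9;67,2 %;42,4 %;MICS 2006
Egypt;97,0 %;98,1 %;10;14;0,7 %;2,3 %;DHS 1995
Eritrea;88,7 %;78,4 %;0;2;38,6 %;33,8 %;DHS 2002
Ethiopia;74,3 %;62,1 %;0;2;6,1 %;4,7 %;DHS 2005
Gambia;76,3 %;77,1 %;0;4;8,9 %;6,6 %;MICS 2010
Ghana;3,8 %;1,5 %;4;14;8 %;6,7 %;MICS 2011
Guinea;96,9 %;94,0 %;0;9;7,5 %;7,7 %;MICS 2012
Guinea-Bissau;49,8 %;48,4 %;0;9;11,8 %;11,4 %;MICS 2010
Iraq;8,1 %;4,9 %;4;10;;;MICS 2011
Kenya;27,1 %;14,6 %;5;14;13,4 %;17,6 %;DHS 2008-09
Liberia;58,3 %;35,9 %;10;15;;;DHS 2007
Mali;91,4 %;90,3 %;0;4;10,6 %;11,1 %;DHS 2012-13
Mauritania;69,4 %;65,9 %;0;4;0 %;0 %;MICS 2011
Niger;2,0 %;1,4 %;0;3;6,3 %;8,0 %;DHS 2012
Nigeria;24,8 %;15,3 %;0;3;5,3 %;3,6 %;DHS 2013
Senegal;25,7 %;24,0 %;0;4;13,8 %;10,9 %;DHS 2010-11
Sierra Leone;89,6 %;74,3 %;8;18;9,0 %;10,1 %;DHS 2013
Somalia;97,9 %;96,7 %;5;9;79,3 %;76,0 %;MICS 2006
Sudan;89,2 %;86,8 %;6;8;82,3 %;73,9 %;DHS 1989-90
Togo;3,9 %;1,1 %;4;14;5,1 %;0 %;MICS 2010
Uganda;1,4 %;1,0 %;8;18;;;DHS 2011
United Republic of Tanzania;14,6 %;7,1 %;0;5;0,7 %;0,8 %;DHS 2010
Yemen;22,6 %;19,3 %;0;1;;;DHS 1997
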