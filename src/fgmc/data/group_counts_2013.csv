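# Register group counts at the 2013-01-01 reference date: first- and
# second-generation female residents per origin country, by analysis group
# (1a arrived past the customary cutting window; 1b/1c arrived at or below it
# and still under 18; 1x arrived at or below it but 18+ at the reference date;
# 2a/2b born in the host country, under/over 18).
# Published cells between 1 and 9 were suppressed at source; here they are
# reconstructed from the printed row and column margins. Where the margins pin
# a cell down uniquely the reconstruction is exact; the remaining small cells
# (Djibouti/Senegal/Togo 1b:1c splits, all cells of the eight pooled
# small countries) are SYNTHETIC allocations chosen once to satisfy the
# printed margins: 1a=28202, 1b=4763, 1c=1456, 2a=9324.
country;g1a;g1b;g1c;g1x;g2a;g2b
Benin;6;0;0;0;1;0
Burkina Faso;7;0;1;0;3;0
Cameroon;204;11;8;0;34;0
Central African Republic;6;0;0;0;2;0
Chad;7;1;1;0;3;0
Côte d'Ivoire;99;11;1;0;15;1
Djibouti;30;2;1;0;10;3
Egypt;203;30;42;0;44;7
Eritrea;4508;218;10;0;606;107
Ethiopia;2707;143;4;0;528;52
Gambia;432;21;3;0;151;47
Ghana;582;133;47;0;226;62
Guinea;73;29;6;0;17;2
Guinea-Bissau;6;0;0;0;2;0
Iraq;7285;1949;416;0;3422;146
Kenya;643;120;64;0;50;17
Liberia;310;100;40;0;74;2
Mali;7;1;2;0;4;1
Mauritania;6;0;1;0;3;0
Niger;6;0;0;0;1;0
Nigeria;529;42;9;0;142;27
Senegal;71;7;1;0;22;1
Sierra Leone;138;54;37;0;49;10
Somalia;8873;1630;593;0;3654;206
Sudan;640;78;116;0;134;9
Togo;38;9;1;0;14;0
Uganda;311;124;44;0;39;16
United Republic of Tanzania;340;42;8;0;36;6
Yemen;135;8;0;0;38;5
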