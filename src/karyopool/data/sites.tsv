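code	region	place	dates	lat	lon	n_larvae
YAR-RY	Yaroslavl region	Rybinsk Reservoir	13.05.1988;11.07.1988;01.08.1988	58°11'59.4"N	38°24'59.5"E	4
NSK-BE	Novosibirsk region	Berdsky Pond, the Shadrikha Rivulet, Berdsk	27.05.1985;18.06.1986;02.06.1987	54°43'60.0"N	83°07'43.4"E	45
NSK-EL	Novosibirsk region	The Eltsovka River, Novosibirsk	14.05.2001;16.05.2001	54°53'22.6"N	83°05'27.5"E	4
NSK-KA	Novosibirsk region	Kainka Lake, Kainskaya Zaimka settlement	20.09.1989;27.04.1991	54°52'13.7"N	83°08'09.7"E	34
NSK-SH	Novosibirsk region	The Shadrikha River, mouth	07.05.2008;12.05.2011;11.05.2012;05.05.2014;04.05.2016;05.05.2017	54°46'41.1"N	83°10'14.0"E	259
NSK-2R	Novosibirsk region	Bol'shaya Protoka Lake, Rechport, Novosibirsk	13.05.2005	54°56'06.5"N	83°03'46.0"E	14
NSK-SP	Novosibirsk region	Pond on the Shipunikha River, Iskitim	07.05.2015	54°34'13.6"N	83°20'42.6"E	1
NSK-LI	Novosibirsk region	Pond on the Koynikha River, Linevo settlement	18.05.2006	54°27'45.5"N	83°20'49.5"E	32
NSK-CH	Novosibirsk region	Pond on the Chernodyrikha River, Ryabchinka village	16.05.2006	54°35'59.9"N	83°07'57.8"E	2
NSK-SA	Novosibirsk region	Pond on the Sarbayan River, Uchastok-Balta village	16.05.2002	55°24'42.3"N	83°56'20.1"E	5
NSK-OR	Novosibirsk region	Pond on the Ora River, Sokur settlement	17.05.2002;12.05.2006	55°12'58.8"N	83°18'06.9"E	52
NSK-YU	Novosibirsk region	Pond on the Tars'ma River, Yurti settlement	14.05.2002;22.05.2004	54°51'04.7"N	84°51'04.9"E	151
NSK-ST	Novosibirsk region	Pond on the Tars'ma River, Stepnogutovo settlement	12.05.2011;12.05.2016	54°51'08.6"N	84°57'31.6"E	54
KEM-TA	Kemerovo region	Tanaevo Lake, Zhuravlevo settlement	14.05.2002	54°46'35.0"N	85°02'52.4"E	1
ALT-GI	Altai territory	Gilovskoye Reservoir	15.05.2003	51°04'14.3"N	81°59'57.7"E	1
ALT-TR	Altai territory	Travinayoe Lake, Oskolkovo settlement	08.05.1994	52°19'11.9"N	83°11'24.2"E	3
KHA-AM	Khabarovsk territory	The Amur River, Khabarovsk	21.06.1987	48°24'56.5"N	135°05'39.4"E	2
KHA-EV	Khabarovsk territory	Evoron Lake	17.07.2006	51°23'02.9"N	136°27'55.8"E	36
YAK-SO	Sakha Republic (Yakutiya)	Solyonoe Lake, Yakutsk vicinity	05.09.1987	61°57'51.3"N	129°37'01.1"E	2
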